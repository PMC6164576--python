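import numpy as np
import pandas as pd
import pytest

from conexnet.core_io import ExpressionMatrix
from conexnet.network import (
    Dendrogram,
    LabeledMatrix,
    NetworkParams,
    cluster_features,
    consensus_tom,
    detect_consensus_modules,
    dynamic_tree_cut,
    merge_close_modules,
    signed_similarity,
    soft_adjacency,
    topological_overlap,
)


def _expr(data, features=None, samples=None):
    data = np.asarray(data, dtype=float)
    features = features or [f"f{i:03d}" for i in range(data.shape[0])]
    samples = samples or [f"s{i}" for i in range(data.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(data, index=features, columns=samples), scale="log_normalized"
    )


def _block_expr(sizes, n_samples, rho, seed, n_noise=0):
    """Features sharing a latent per block, plus optional pure-noise features."""
    rng = np.random.default_rng(seed)
    rows = []
    for b, size in enumerate(sizes):
        latent = rng.standard_normal(n_samples)
        for _ in range(size):
            rows.append(rho * latent + np.sqrt(1 - rho**2) * rng.standard_normal(n_samples))
    for _ in range(n_noise):
        rows.append(rng.standard_normal(n_samples))
    return _expr(np.vstack(rows))


class TestSignedSimilarity:
    def test_correlation_endpoints(self):
        x = np.arange(6, dtype=float)
        em = _expr(np.vstack([x, x * 2 + 1, -x, np.sin(x)]))
        s = signed_similarity(em).values
        assert s[0, 1] == pytest.approx(1.0)  # perfectly correlated
        assert s[0, 2] == pytest.approx(0.0)  # perfectly anticorrelated
        assert np.all(np.diag(s) == 1.0)

    def test_uncorrelated_near_half(self):
        rng = np.random.default_rng(0)
        em = _expr(rng.standard_normal((2, 5000)))
        s = signed_similarity(em).values
        assert s[0, 1] == pytest.approx(0.5, abs=0.03)

    def test_zero_variance_feature_named(self):
        em = _expr([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="f000"):
            signed_similarity(em)


class TestSoftAdjacency:
    def test_half_to_the_ninth(self):
        sim = LabeledMatrix(["a", "b"], np.array([[1.0, 0.5], [0.5, 1.0]]))
        adj = soft_adjacency(sim, beta=9)
        assert adj.values[0, 1] == pytest.approx(0.001953125)
        assert adj.values[0, 0] == 0.0  # diagonal zeroed for connectivity

    def test_unit_similarity_fixed_point(self):
        sim = LabeledMatrix(["a", "b"], np.ones((2, 2)))
        assert soft_adjacency(sim, beta=7).values[0, 1] == 1.0

    def test_beta_one_is_identity_off_diagonal(self):
        vals = np.array([[1.0, 0.3], [0.3, 1.0]])
        adj = soft_adjacency(LabeledMatrix(["a", "b"], vals), beta=1)
        assert adj.values[0, 1] == pytest.approx(0.3)


class TestTopologicalOverlap:
    def test_two_nodes_tom_equals_adjacency(self):
        a = np.array([[0.0, 0.4], [0.4, 0.0]])
        tom = topological_overlap(LabeledMatrix(["a", "b"], a))
        assert tom.values[0, 1] == pytest.approx(0.4)

    def test_equal_triangle_tom_equals_a(self):
        for a_val in (0.2, 0.5, 0.8):
            a = np.full((3, 3), a_val)
            np.fill_diagonal(a, 0.0)
            tom = topological_overlap(LabeledMatrix(list("abc"), a))
            off = tom.values[~np.eye(3, dtype=bool)]
            np.testing.assert_allclose(off, a_val, rtol=1e-12)

    def test_zero_adjacency_zero_overlap(self):
        tom = topological_overlap(LabeledMatrix(list("abc"), np.zeros((3, 3))))
        assert np.all(tom.values[~np.eye(3, dtype=bool)] == 0.0)
        assert np.all(np.diag(tom.values) == 1.0)

    def test_range_and_symmetry_on_random_input(self, rng):
        s = rng.uniform(0, 1, size=(20, 20))
        s = (s + s.T) / 2
        np.fill_diagonal(s, 1.0)
        adj = soft_adjacency(LabeledMatrix([f"f{i}" for i in range(20)], s), beta=6)
        tom = topological_overlap(adj)
        assert np.all(tom.values >= 0) and np.all(tom.values <= 1)
        np.testing.assert_allclose(tom.values, tom.values.T, atol=1e-12)


class TestConsensusTOM:
    def _lm(self, vals):
        n = vals.shape[0]
        return LabeledMatrix([f"f{i}" for i in range(n)], vals)

    def test_identical_inputs_unchanged(self, rng):
        v = rng.uniform(0, 1, size=(5, 5))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        out = consensus_tom([self._lm(v), self._lm(v)])
        np.testing.assert_allclose(out.values, v, atol=1e-12)

    def test_zero_input_zeroes_consensus(self, rng):
        v = rng.uniform(0, 1, size=(4, 4))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        zero = np.zeros((4, 4))
        np.fill_diagonal(zero, 1.0)
        out = consensus_tom([self._lm(v), self._lm(zero)], quantile=0.0)
        assert np.all(out.values[~np.eye(4, dtype=bool)] == 0.0)

    def test_minimum_matches_brute_force_without_calibration(self, rng):
        a = rng.uniform(0, 1, size=(3, 3))
        a = (a + a.T) / 2
        b = rng.uniform(0, 1, size=(3, 3))
        b = (b + b.T) / 2
        np.fill_diagonal(a, 1.0)
        np.fill_diagonal(b, 1.0)
        out = consensus_tom([self._lm(a), self._lm(b)], quantile=0.0, calibrate=False)
        expected = np.minimum(a, b)
        np.fill_diagonal(expected, 1.0)
        np.testing.assert_allclose(out.values, expected, atol=1e-12)

    def test_consensus_below_calibrated_inputs(self, rng):
        mats = []
        for _ in range(3):
            v = rng.uniform(0, 1, size=(6, 6))
            v = (v + v.T) / 2
            np.fill_diagonal(v, 1.0)
            mats.append(self._lm(v))
        out = consensus_tom(mats, quantile=0.0, calibrate=False)
        for m in mats:
            off = ~np.eye(6, dtype=bool)
            assert np.all(out.values[off] <= m.values[off] + 1e-12)

    def test_differing_feature_sets_rejected(self):
        a = LabeledMatrix(["x", "y"], np.eye(2))
        b = LabeledMatrix(["x", "z"], np.eye(2))
        with pytest.raises(ValueError, match="feature sets differ"):
            consensus_tom([a, b])


class TestClustering:
    def test_two_features_single_merge(self):
        tom = LabeledMatrix(["a", "b"], np.array([[1.0, 0.7], [0.7, 1.0]]))
        dend = cluster_features(tom)
        assert len(dend.linkage) == 1
        assert dend.max_height == pytest.approx(0.3)

    def test_merge_heights_invariant_to_feature_order(self, rng):
        n = 12
        v = rng.uniform(0, 1, size=(n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        ids = [f"f{i:02d}" for i in range(n)]
        tom1 = LabeledMatrix(ids, v)
        perm = rng.permutation(n)
        tom2 = LabeledMatrix([ids[i] for i in perm], v[np.ix_(perm, perm)])
        h1 = cluster_features(tom1).linkage[:, 2]
        h2 = cluster_features(tom2).linkage[:, 2]
        np.testing.assert_allclose(h1, h2, atol=1e-12)

    def test_block_diagonal_final_merge_at_one(self):
        n = 6
        v = np.zeros((n, n))
        v[:3, :3] = 1.0
        v[3:, 3:] = 1.0
        tom = LabeledMatrix([f"f{i}" for i in range(n)], v)
        dend = cluster_features(tom)
        assert dend.max_height == pytest.approx(1.0)

    def test_heights_must_be_monotone(self):
        bad = np.array([[0, 1, 0.5, 2], [2, 3, 0.2, 3]], dtype=float)
        with pytest.raises(ValueError, match="non-decreasing"):
            Dendrogram(feature_ids=list("abcd"), linkage=bad)


class TestDynamicTreeCut:
    def test_two_planted_blocks_recovered(self):
        expr = _block_expr([25, 25], n_samples=40, rho=0.95, seed=1)
        tom = topological_overlap(soft_adjacency(signed_similarity(expr), 9))
        assignment = dynamic_tree_cut(cluster_features(tom), min_module_size=20)
        sizes = sorted(assignment.module_sizes.values())
        assert sizes == [25, 25]
        assert assignment.grey_fraction == 0.0

    def test_single_small_block_all_grey(self):
        expr = _block_expr([10], n_samples=30, rho=0.95, seed=2)
        tom = topological_overlap(soft_adjacency(signed_similarity(expr), 9))
        assignment = dynamic_tree_cut(cluster_features(tom), min_module_size=20)
        assert assignment.grey_fraction == 1.0
        assert assignment.color_order == []

    def test_largest_module_is_labeled_first(self):
        expr = _block_expr([30, 22], n_samples=40, rho=0.95, seed=3)
        tom = topological_overlap(soft_adjacency(signed_similarity(expr), 9))
        assignment = dynamic_tree_cut(cluster_features(tom), min_module_size=20)
        sizes = assignment.module_sizes
        assert assignment.color_order[0] == "turquoise"
        assert sizes["turquoise"] == max(sizes.values())

    def test_min_module_size_validation(self):
        dend = Dendrogram(["a", "b"], np.array([[0, 1, 0.5, 2]], dtype=float))
        with pytest.raises(ValueError, match="min_module_size"):
            dynamic_tree_cut(dend, min_module_size=1)


class TestMergeCloseModules:
    def _two_condition_split_module(self, seed=0):
        """One latent split across two detected labels in both conditions."""
        rng = np.random.default_rng(seed)
        mats = {}
        for cond in ("A", "B"):
            latent = rng.standard_normal(30)
            rows = [
                0.9 * latent + np.sqrt(1 - 0.81) * rng.standard_normal(30)
                for _ in range(10)
            ]
            rows += [rng.standard_normal(30) for _ in range(4)]
            mats[cond] = _expr(
                np.vstack(rows), samples=[f"{cond}{i}" for i in range(30)]
            )
        labels = pd.Series(
            ["m1"] * 5 + ["m2"] * 5 + ["grey"] * 4, index=mats["A"].feature_ids
        )
        from conexnet.network import ModuleAssignment

        return ModuleAssignment(labels=labels, color_order=["m1", "m2"]), mats

    def test_correlated_fragments_are_merged(self):
        assignment, mats = self._two_condition_split_module()
        merged = merge_close_modules(assignment, mats, merge_cut_height=0.25)
        assert len(merged.color_order) == 1
        assert merged.module_sizes[merged.color_order[0]] == 10

    def test_orthogonal_modules_unchanged(self):
        rng = np.random.default_rng(5)
        mats = {}
        for cond in ("A", "B"):
            l1, l2 = rng.standard_normal((2, 30))
            rows = [0.95 * l1 + 0.05 * rng.standard_normal(30) for _ in range(5)]
            rows += [0.95 * l2 + 0.05 * rng.standard_normal(30) for _ in range(5)]
            mats[cond] = _expr(np.vstack(rows), samples=[f"{cond}{i}" for i in range(30)])
        from conexnet.network import ModuleAssignment

        labels = pd.Series(["m1"] * 5 + ["m2"] * 5, index=mats["A"].feature_ids)
        assignment = ModuleAssignment(labels=labels, color_order=["m1", "m2"])
        merged = merge_close_modules(assignment, mats, merge_cut_height=0.25)
        assert len(merged.color_order) == 2


class TestDetectConsensusModules:
    def test_duplicated_condition_equals_single_set_structure(self):
        expr = _block_expr([25, 25], n_samples=20, rho=0.95, seed=7, n_noise=5)
        renamed = ExpressionMatrix(
            expr.values.rename(columns=lambda s: s + "_dup"), scale="log_normalized"
        )
        assignment, _, cons = detect_consensus_modules(
            {"A": expr, "B": renamed}, NetworkParams()
        )
        single_tom = topological_overlap(soft_adjacency(signed_similarity(expr), 9))
        np.testing.assert_allclose(cons.values, single_tom.values, atol=1e-10)
        assert sorted(assignment.module_sizes.values()) == [25, 25]

    def test_requires_two_conditions(self, small_expr):
        with pytest.raises(ValueError, match="at least 2 conditions"):
            detect_consensus_modules({"A": small_expr})

    def test_feature_order_invariance(self):
        exprs = {}
        for cond, seed in (("A", 21), ("B", 22)):
            em = _block_expr([22, 24], n_samples=18, rho=0.9, seed=seed, n_noise=6)
            exprs[cond] = ExpressionMatrix(
                em.values.set_axis([f"g{i:02d}" for i in range(52)]),
                scale="log_normalized",
            )
            exprs[cond] = ExpressionMatrix(
                exprs[cond].values.rename(columns=lambda s: f"{cond}_{s}"),
                scale="log_normalized",
            )
        a1, _, _ = detect_consensus_modules(exprs, NetworkParams())
        perm = np.random.default_rng(9).permutation(52)
        shuffled = {
            c: ExpressionMatrix(e.values.iloc[perm], scale="log_normalized")
            for c, e in exprs.items()
        }
        a2, _, _ = detect_consensus_modules(shuffled, NetworkParams())
        joined = pd.concat(
            [a1.labels.rename("one"), a2.labels.rename("two")], axis=1
        )
        assert (joined["one"] == joined["two"]).all()
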