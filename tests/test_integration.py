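import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conexnet.core_io import (
    ExpressionMatrix,
    PhenotypeTable,
    TargetPredictionTable,
    load_fixture,
)
from conexnet.integration import (
    bh_adjust,
    build_triples,
    count_triples,
    feature_trait_correlations,
    filter_targets,
    min_fdr_pair,
    normalize_trait_label,
    pair_correlations,
    restrict_to_expressed,
)


def brute_force_bh(p):
    """Independent step-up oracle: q_i = min_{j: p_j >= p_i} m * p_(j) / rank_j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running_min = np.inf
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running_min = min(running_min, m * p[i] / (pos + 1))
        q[i] = min(running_min, 1.0)
    return q


class TestBHAdjust:
    def test_hand_worked_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_equal_pvalues_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_single_pvalue_identity(self):
        np.testing.assert_allclose(bh_adjust([0.123]), [0.123])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40),
    )
    def test_matches_brute_force_oracle(self, pvals):
        np.testing.assert_allclose(bh_adjust(pvals), brute_force_bh(pvals), atol=1e-12)

    def test_matches_statsmodels_reference(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=200)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), q_ref, atol=1e-12)


def _targets(rows):
    return TargetPredictionTable(
        pd.DataFrame(rows, columns=["mirna_id", "gene_id", "context_score", "context_percentile"])
    )


class TestTargetFilters:
    def test_percentile_cut_inclusive(self):
        rows = [(f"m{i}", f"g{i}", -0.5, float(i)) for i in range(1, 101)]
        out = filter_targets(_targets(rows), 95)
        assert len(out) == 6  # percentiles 95..100

    def test_strict_cut_drops_boundary(self):
        rows = [(f"m{i}", f"g{i}", -0.5, float(i)) for i in range(1, 101)]
        assert len(filter_targets(_targets(rows), 95, strict=True)) == 5

    def test_empty_and_zero_cut(self):
        empty = _targets([])
        assert len(filter_targets(empty, 95)) == 0
        rows = [("m", "g", -0.1, 10.0)]
        assert len(filter_targets(_targets(rows), 0)) == 1

    def test_restrict_matches_set_intersection(self, rng):
        genes = [f"g{i}" for i in range(30)]
        rows = [(f"m{i % 3}", g, -0.2, 96.0) for i, g in enumerate(genes)]
        expressed = rng.choice(genes, size=12, replace=False)
        expr = ExpressionMatrix(
            pd.DataFrame(
                rng.standard_normal((12, 4)), index=list(expressed), columns=list("abcd")
            ),
            scale="log_normalized",
        )
        out = restrict_to_expressed(_targets(rows), expr)
        assert set(out.table["gene_id"]) == set(expressed)

    def test_filters_commute_and_are_idempotent(self, rng):
        rows = [
            (f"m{i}", f"g{i}", -0.3, float(rng.uniform(80, 100))) for i in range(40)
        ]
        t = _targets(rows)
        expr = ExpressionMatrix(
            pd.DataFrame(
                rng.standard_normal((20, 4)),
                index=[f"g{i}" for i in range(0, 40, 2)],
                columns=list("abcd"),
            ),
            scale="log_normalized",
        )
        ab = restrict_to_expressed(filter_targets(t, 95), expr)
        ba = filter_targets(restrict_to_expressed(t, expr), 95)
        pd.testing.assert_frame_equal(ab.table, ba.table)
        again = filter_targets(ab, 95)
        pd.testing.assert_frame_equal(again.table, ab.table)


class TestPairCorrelations:
    def _setup(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(20)
        mirna = ExpressionMatrix(
            pd.DataFrame([x], index=["mirA"], columns=[f"s{i}" for i in range(20)]),
            scale="log_normalized",
        )
        genes = pd.DataFrame(
            [-x, x, rng.standard_normal(20)],
            index=["gNeg", "gPos", "gNoise"],
            columns=[f"s{i}" for i in range(20)],
        )
        mrna = ExpressionMatrix(genes, scale="log_normalized")
        targets = _targets(
            [("mirA", "gNeg", -0.4, 97.0), ("mirA", "gPos", -0.4, 97.0), ("mirA", "gNoise", -0.4, 97.0)]
        )
        assignment = pd.Series({"mirA": "blue"})
        return mirna, mrna, targets, assignment

    def test_perfect_negative_is_coexpressed(self):
        mirna, mrna, targets, assignment = self._setup()
        pairs = pair_correlations(mirna, mrna, targets, assignment)
        neg = pairs[pairs["gene"] == "gNeg"].iloc[0]
        assert neg["r_pair"] == pytest.approx(-1.0)
        assert neg["coexpressed"]

    def test_positive_correlation_never_coexpressed(self):
        mirna, mrna, targets, assignment = self._setup()
        pairs = pair_correlations(mirna, mrna, targets, assignment)
        pos = pairs[pairs["gene"] == "gPos"].iloc[0]
        assert pos["r_pair"] == pytest.approx(1.0)
        assert not pos["coexpressed"]

    def test_grey_mirnas_skipped(self):
        mirna, mrna, targets, _ = self._setup()
        pairs = pair_correlations(mirna, mrna, targets, pd.Series({"mirA": "grey"}))
        assert pairs.empty

    def test_no_shared_samples_errors(self):
        mirna, mrna, targets, assignment = self._setup()
        renamed = ExpressionMatrix(
            mrna.values.rename(columns=lambda s: s + "_x"), scale="log_normalized"
        )
        with pytest.raises(ValueError, match="shared samples"):
            pair_correlations(mirna, renamed, targets, assignment)


class TestFeatureTrait:
    def test_trait_equal_to_feature(self, rng):
        x = rng.standard_normal(15)
        expr = ExpressionMatrix(
            pd.DataFrame([x], index=["f"], columns=[f"s{i}" for i in range(15)]),
            scale="log_normalized",
        )
        phen = PhenotypeTable(
            pd.DataFrame({"t": x}, index=[f"s{i}" for i in range(15)])
        )
        out = feature_trait_correlations(expr, phen)
        assert out.iloc[0]["r"] == pytest.approx(1.0)
        assert out.iloc[0]["significant"]

    def test_permuted_trait_rarely_significant(self):
        rng = np.random.default_rng(1)
        n_sig = 0
        n_tot = 0
        for _ in range(20):
            expr = ExpressionMatrix(
                pd.DataFrame(
                    rng.standard_normal((5, 30)),
                    index=[f"f{i}" for i in range(5)],
                    columns=[f"s{i}" for i in range(30)],
                ),
                scale="log_normalized",
            )
            phen = PhenotypeTable(
                pd.DataFrame(
                    {"t": rng.permutation(expr.values.iloc[0].to_numpy())},
                    index=expr.sample_ids,
                )
            )
            out = feature_trait_correlations(expr, phen)
            n_sig += int(out["significant"].sum())
            n_tot += len(out)
        assert n_sig / n_tot <= 0.1


class TestTriples:
    def test_table6_reconstruction_counts(self):
        t6 = load_fixture("table6").table
        by_mod = count_triples(t6, by="module")
        assert by_mod.to_dict() == {"Blue": 68, "Brown": 6, "Turquoise": 2}
        by_trait = count_triples(t6, by="trait")
        assert by_trait["milk yield"] == 28
        assert by_trait["protein yield"] == 31
        assert by_trait["protein percentage"] == 5

    def test_trait_label_matching_is_case_insensitive(self):
        assert normalize_trait_label(" Protein  Yield ") == "protein yield"

    def test_min_fdr_pairs_from_reference_table(self):
        t6 = load_fixture("table6").table
        assert min_fdr_pair(t6, "Blue") == ("bta-miR-183", "RHBDD2", 0.003)
        assert min_fdr_pair(t6, "Brown") == ("bta-miR-484", "EIF1AD", 0.011)
        assert min_fdr_pair(t6, "Turquoise") == ("bta-miR-130a", "SBSPON", 0.004)

    def test_min_fdr_absent_module_errors(self):
        t6 = load_fixture("table6").table
        with pytest.raises(ValueError, match="not present"):
            min_fdr_pair(t6, "Green")

    def test_empty_inputs_give_empty_table(self):
        pairs = pd.DataFrame(
            columns=["mirna", "gene", "module", "context_percentile", "r_pair", "p_pair", "fdr_pair", "coexpressed"]
        )
        ft = pd.DataFrame(columns=["feature", "trait", "r", "p", "fdr", "significant"])
        out = build_triples(pairs, ft, ft)
        assert out.empty
        assert count_triples(out, by="module").empty

    def test_pair_significant_for_two_traits_yields_two_rows(self):
        pairs = pd.DataFrame(
            [
                {
                    "mirna": "m1",
                    "gene": "g1",
                    "module": "blue",
                    "context_percentile": 97.0,
                    "r_pair": -0.6,
                    "p_pair": 0.001,
                    "fdr_pair": 0.004,
                    "coexpressed": True,
                }
            ]
        )
        mt = pd.DataFrame(
            [
                {"feature": "m1", "trait": "Milk yield", "r": -0.6, "p": 0.001, "fdr": 0.01},
                {"feature": "m1", "trait": "protein yield", "r": -0.5, "p": 0.005, "fdr": 0.02},
            ]
        )
        gt = pd.DataFrame(
            [
                {"feature": "g1", "trait": "milk yield", "r": 0.6, "p": 0.001, "fdr": 0.01},
                {"feature": "g1", "trait": "Protein yield", "r": 0.5, "p": 0.004, "fdr": 0.02},
            ]
        )
        out = build_triples(pairs, mt, gt)
        assert len(out) == 2
        # every emitted record satisfies the thresholds by construction
        assert (out["fdr_pair"] < 0.05).all()
        assert (out["r_pair"] < 0).all()
        assert (out["fdr_mirna_trait"] < 0.05).all()
        assert (out["fdr_gene_trait"] < 0.05).all()

    def test_unknown_grouping_key_rejected(self):
        t6 = load_fixture("table6").table
        with pytest.raises(ValueError, match="grouping key"):
            count_triples(t6, by="gene")
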