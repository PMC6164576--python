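"""Synthetic multi-condition datasets with planted co-expression structure.

The generator emulates the study design the pipeline targets: a few hundred
miRNAs measured as counts in three dietary conditions of a dozen samples
each, a few thousand mRNAs, a 33-trait phenotype table and a
target-prediction table.  Co-expression modules are planted with a
shared-latent-factor model: each module m has, per condition c, a latent
eigengene e_{c,m} ~ N(0, 1) over that condition's samples, and member i has
log-expression

    x_i = rho_i * e_{c,m} + sqrt(1 - rho_i^2) * eps,   eps ~ N(0, 1),

so the population correlation of two members is rho_i * rho_j.  Latents are
drawn independently per condition: module membership, not eigengene values,
is the cross-condition invariant.  Counts arise by exponentiating the log
signal to a negative-binomial mean and applying per-sample library-size
factors.  Traits are linked to module latents at a target correlation r, and
target mRNAs are negatively regulated (y = gamma * x_i + noise, gamma < 0).

The target table mixes three row kinds: true regulatory links at context
percentile >= 95; high-percentile decoys (>= 95, connecting module miRNAs to
unrelated genes) that the negative-correlation filter must reject; and
low-percentile decoys (< 95) that the percentile filter removes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .core_io import (
    ConditionMap,
    ExpressionMatrix,
    PhenotypeTable,
    TargetPredictionTable,
)

DEFAULT_CONDITIONS = ("control", "linseed", "safflower")


@dataclass
class TraitLink:
    trait: str
    module: int  # 1-based planted module index
    r: float


@dataclass
class TargetLink:
    mirna: str
    gene: str
    gamma: float  # regulation coefficient, < 0 for true links


@dataclass
class SyntheticConfig:
    """Study-scale defaults: 321 miRNAs, modules (70, 34, 86), 3 x 12 samples."""

    n_mirna: int = 321
    n_mrna: int = 1500
    n_samples_per_condition: int = 12
    n_conditions: int = 3
    module_sizes: tuple[int, ...] = (70, 34, 86)
    loading_range: tuple[float, float] = (0.8, 0.95)
    n_traits: int = 33
    n_linked_traits_per_module: int = 1
    trait_link_r: float = 0.9
    n_true_targets_per_module: int = 15
    target_gamma: float = -0.8
    n_decoy_targets_high: int = 60
    n_decoy_targets_low: int = 100
    nb_dispersion: float = 0.05
    base_mean_range: tuple[float, float] = (50.0, 5000.0)
    library_size_range: tuple[float, float] = (0.5, 2.0)
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.module_sizes) > self.n_mirna:
            raise ValueError("module sizes exceed the number of miRNAs")
        if any(s < 2 for s in self.module_sizes):
            raise ValueError("every planted module needs at least 2 members")
        if len(self.conditions) < self.n_conditions:
            self.conditions = tuple(f"cond{i + 1}" for i in range(self.n_conditions))
        else:
            self.conditions = tuple(self.conditions[: self.n_conditions])


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset."""

    module_assignment: pd.Series  # feature -> module index (0 = background)
    module_latents: dict[tuple[str, int], np.ndarray]
    mirna_loadings: pd.Series  # feature -> rho (0 for background)
    trait_links: list[TraitLink]
    target_links: list[TargetLink]
    log_expression: pd.DataFrame  # latent log signal, features x all samples
    seed: int


@dataclass
class SyntheticDataset:
    mirna_counts: ExpressionMatrix  # all samples, counts scale
    condition_map: ConditionMap
    mrna_expr: ExpressionMatrix  # log scale
    phenotypes: PhenotypeTable
    targets: TargetPredictionTable
    truth: SyntheticTruth
    config: SyntheticConfig = field(repr=False, default=None)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draw with Var = mu + dispersion * mu^2; Poisson when dispersion = 0."""
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_dataset(config: SyntheticConfig | None = None, seed: int | None = None) -> SyntheticDataset:
    """Generate a complete dataset plus ground truth; fully seeded."""
    config = config or SyntheticConfig()
    if seed is not None:
        config = SyntheticConfig(**{**config.__dict__, "seed": seed})
    rng = np.random.default_rng(config.seed)

    conds = list(config.conditions)
    nspc = config.n_samples_per_condition
    sample_ids = [f"{c}_s{j + 1:02d}" for c in conds for j in range(nspc)]
    cond_of = {s: c for s in sample_ids for c in [s.rsplit("_s", 1)[0]]}
    mirna_ids = [f"mir-{i + 1:04d}" for i in range(config.n_mirna)]
    gene_ids = [f"gene-{g + 1:05d}" for g in range(config.n_mrna)]

    # planted membership: modules occupy leading features, background trails
    assignment = np.zeros(config.n_mirna, dtype=int)
    pos = 0
    for k, size in enumerate(config.module_sizes, start=1):
        assignment[pos : pos + size] = k
        pos += size
    loadings = np.zeros(config.n_mirna)
    lo, hi = config.loading_range
    in_module = assignment > 0
    loadings[in_module] = rng.uniform(lo, hi, size=in_module.sum())

    # latent log-expression per condition
    latents: dict[tuple[str, int], np.ndarray] = {}
    x = np.empty((config.n_mirna, len(sample_ids)))
    for ci, cond in enumerate(conds):
        cols = slice(ci * nspc, (ci + 1) * nspc)
        for k in range(1, len(config.module_sizes) + 1):
            latents[(cond, k)] = rng.standard_normal(nspc)
        eps = rng.standard_normal((config.n_mirna, nspc))
        for i in range(config.n_mirna):
            k = assignment[i]
            if k == 0:
                x[i, cols] = eps[i]
            else:
                rho = loadings[i]
                x[i, cols] = rho * latents[(cond, k)] + np.sqrt(1 - rho * rho) * eps[i]

    # counts: NB around library-size-scaled exponentiated means
    base = np.exp(
        rng.uniform(
            np.log(config.base_mean_range[0]),
            np.log(config.base_mean_range[1]),
            size=config.n_mirna,
        )
    )
    lib_lo, lib_hi = config.library_size_range
    lib = np.exp(rng.uniform(np.log(lib_lo), np.log(lib_hi), size=len(sample_ids)))
    mu = base[:, None] * np.power(2.0, x) * lib[None, :]
    counts = _nb_counts(rng, mu, config.nb_dispersion).astype(float)
    mirna_counts = ExpressionMatrix(
        pd.DataFrame(counts, index=mirna_ids, columns=sample_ids), scale="counts"
    )

    # traits: linked traits follow the module latent at correlation r
    trait_names = [f"trait_{t + 1:02d}" for t in range(config.n_traits)]
    traits = rng.standard_normal((len(sample_ids), config.n_traits))
    trait_links: list[TraitLink] = []
    t_idx = 0
    for k in range(1, len(config.module_sizes) + 1):
        for _ in range(config.n_linked_traits_per_module):
            if t_idx >= config.n_traits:
                break
            r = config.trait_link_r
            for ci, cond in enumerate(conds):
                cols = slice(ci * nspc, (ci + 1) * nspc)
                eta = rng.standard_normal(nspc)
                traits[cols, t_idx] = r * latents[(cond, k)] + np.sqrt(1 - r * r) * eta
            trait_links.append(TraitLink(trait=trait_names[t_idx], module=k, r=r))
            t_idx += 1
    phenotypes = PhenotypeTable(
        pd.DataFrame(traits, index=sample_ids, columns=trait_names)
    )

    # target links: true regulated genes, then decoys
    target_rows: list[dict] = []
    target_links: list[TargetLink] = []
    mrna = rng.standard_normal((config.n_mrna, len(sample_ids)))
    gene_cursor = 0
    module_members = {
        k: [mirna_ids[i] for i in np.flatnonzero(assignment == k)]
        for k in range(1, len(config.module_sizes) + 1)
    }
    x_std = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
    for k, members in module_members.items():
        # regulatory links attach to the highest-loading (most representative)
        # members, mirroring the hub-centred target analysis downstream
        ranked = sorted(members, key=lambda m: -loadings[mirna_ids.index(m)])
        chosen = ranked[: config.n_true_targets_per_module]
        for m, mirna in enumerate(chosen):
            gene = gene_ids[gene_cursor]
            gene_cursor += 1
            i = mirna_ids.index(mirna)
            gamma = config.target_gamma
            noise = rng.standard_normal(len(sample_ids))
            mrna[gene_cursor - 1] = gamma * x_std[i] + np.sqrt(1 - gamma * gamma) * noise
            target_links.append(TargetLink(mirna=mirna, gene=gene, gamma=gamma))
            target_rows.append(
                {
                    "mirna_id": mirna,
                    "gene_id": gene,
                    "context_score": -float(rng.uniform(0.3, 0.9)),
                    "context_percentile": float(rng.uniform(95, 100)),
                }
            )

    decoy_genes = gene_ids[gene_cursor:]
    module_mirnas = [m for members in module_members.values() for m in members]
    used = {(r["mirna_id"], r["gene_id"]) for r in target_rows}

    def _add_decoys(n: int, pct_lo: float, pct_hi: float) -> None:
        if not module_mirnas or not decoy_genes:
            return
        available = len(module_mirnas) * len(decoy_genes) - sum(
            1 for m, g in used if g in set(decoy_genes)
        )
        n = min(n, available)
        added = 0
        while added < n:
            mirna = module_mirnas[int(rng.integers(len(module_mirnas)))]
            gene = decoy_genes[int(rng.integers(len(decoy_genes)))]
            if (mirna, gene) in used:
                continue
            used.add((mirna, gene))
            target_rows.append(
                {
                    "mirna_id": mirna,
                    "gene_id": gene,
                    "context_score": -float(rng.uniform(0.05, 0.5)),
                    "context_percentile": float(rng.uniform(pct_lo, pct_hi)),
                }
            )
            added += 1

    _add_decoys(config.n_decoy_targets_high, 95.0, 100.0)
    _add_decoys(config.n_decoy_targets_low, 0.0, 95.0)

    targets = TargetPredictionTable(
        pd.DataFrame.from_records(
            target_rows,
            columns=["mirna_id", "gene_id", "context_score", "context_percentile"],
        )
    )
    mrna_expr = ExpressionMatrix(
        pd.DataFrame(mrna, index=gene_ids, columns=sample_ids), scale="log_normalized"
    )

    truth = SyntheticTruth(
        module_assignment=pd.Series(assignment, index=mirna_ids),
        module_latents=latents,
        mirna_loadings=pd.Series(loadings, index=mirna_ids),
        trait_links=trait_links,
        target_links=target_links,
        log_expression=pd.DataFrame(x, index=mirna_ids, columns=sample_ids),
        seed=config.seed,
    )
    return SyntheticDataset(
        mirna_counts=mirna_counts,
        condition_map=ConditionMap(cond_of),
        mrna_expr=mrna_expr,
        phenotypes=phenotypes,
        targets=targets,
        truth=truth,
        config=config,
    )


def truth_module_labels(truth: SyntheticTruth) -> pd.Series:
    """Feature -> integer label (0 = background), for adjusted-Rand comparison."""
    return truth.module_assignment.copy()


def expected_pair_correlation(truth: SyntheticTruth, feat_i: str, feat_j: str) -> float:
    """Population correlation rho_i * rho_j for same-module pairs, else 0."""
    ki = truth.module_assignment[feat_i]
    kj = truth.module_assignment[feat_j]
    if ki == 0 or ki != kj:
        return 0.0
    return float(truth.mirna_loadings[feat_i] * truth.mirna_loadings[feat_j])


def recovery_ari(assignment_labels: pd.Series, truth: SyntheticTruth) -> float:
    """Adjusted Rand index between detected labels and the planted modules.

    ``assignment_labels`` may be colour labels (grey = background) or
    integers; alignment is by feature id.
    """
    t = truth_module_labels(truth)
    detected = assignment_labels.reindex(t.index)
    codes = pd.factorize(detected.fillna("grey"))[0]
    return float(adjusted_rand_score(t.to_numpy(), codes))
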