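"""miRNA-mRNA-trait integration.

Predicted targets are filtered to strong sites (context++ percentile >= 95)
present in the expressed-mRNA matrix; miRNA-mRNA Pearson correlations are
tested with Benjamini-Hochberg FDR within each module's family, and a pair
is called co-expressed when its correlation is negative and FDR < 0.05.
Feature-trait correlations (one BH family per feature kind) complete the
three-way records: a (miRNA, gene, trait) triple is emitted when the pair is
co-expressed and both members correlate significantly with the same trait.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, PhenotypeTable, TargetPredictionTable
from .module_trait import correlation_with_p

logger = logging.getLogger(__name__)

TRIPLE_COLUMNS = [
    "module",
    "mirna",
    "gene",
    "context_percentile",
    "r_pair",
    "fdr_pair",
    "trait",
    "r_mirna_trait",
    "fdr_mirna_trait",
    "r_gene_trait",
    "fdr_gene_trait",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1.

    q_(i) = min_{j >= i} m * p_(j) / j on the sorted p-values, reported in
    the original order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def normalize_trait_label(label: str) -> str:
    """Case-insensitive trait matching with whitespace collapsing."""
    return re.sub(r"\s+", " ", str(label).strip()).lower()


def filter_targets(
    targets: TargetPredictionTable, percentile_cut: float = 95.0, strict: bool = False
) -> TargetPredictionTable:
    """Keep rows at or above the context++ percentile cut.

    The default is inclusive (the top 5% of sites); ``strict=True`` drops
    boundary rows.
    """
    pct = targets.table["context_percentile"]
    keep = pct > percentile_cut if strict else pct >= percentile_cut
    return TargetPredictionTable(targets.table[keep].reset_index(drop=True))


def restrict_to_expressed(
    targets: TargetPredictionTable, mrna_expr: ExpressionMatrix
) -> TargetPredictionTable:
    """Keep rows whose gene is a feature of the expressed-mRNA matrix."""
    expressed = set(mrna_expr.feature_ids)
    keep = targets.table["gene_id"].isin(expressed)
    kept = int(keep.sum())
    if kept == 0:
        logger.warning("no predicted target genes overlap the mRNA matrix")
    logger.info("expressed-gene filter kept %d of %d target rows", kept, len(targets.table))
    return TargetPredictionTable(targets.table[keep].reset_index(drop=True))


def pair_correlations(
    mirna_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    targets: TargetPredictionTable,
    assignment: pd.Series,
    fdr_threshold: float = 0.05,
    family: str = "module",
) -> pd.DataFrame:
    """Pearson r, p and BH FDR for each candidate miRNA-mRNA pair.

    ``assignment`` maps miRNA id -> module label; only miRNAs present in the
    mapping are tested.  BH is applied within each module's family of pairs
    by default (``family="global"`` adjusts over all pairs at once).  The
    ``coexpressed`` flag requires r < 0 and FDR below the threshold.
    """
    shared = [s for s in mirna_expr.sample_ids if s in set(mrna_expr.sample_ids)]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples between the matrices")
    mirna_vals = mirna_expr.subset_samples(shared)
    mrna_vals = mrna_expr.subset_samples(shared)
    rows = []
    mirna_set = set(mirna_expr.feature_ids)
    gene_set = set(mrna_expr.feature_ids)
    for rec in targets.table.itertuples(index=False):
        if rec.mirna_id not in mirna_set or rec.gene_id not in gene_set:
            continue
        module = assignment.get(rec.mirna_id)
        if module is None or module == "grey":
            continue
        r, p = correlation_with_p(
            mirna_vals.values.loc[rec.mirna_id], mrna_vals.values.loc[rec.gene_id]
        )
        rows.append(
            {
                "mirna": rec.mirna_id,
                "gene": rec.gene_id,
                "module": module,
                "context_percentile": rec.context_percentile,
                "r_pair": r,
                "p_pair": p,
            }
        )
    df = pd.DataFrame.from_records(
        rows,
        columns=["mirna", "gene", "module", "context_percentile", "r_pair", "p_pair"],
    )
    if df.empty:
        df["fdr_pair"] = pd.Series(dtype=float)
        df["coexpressed"] = pd.Series(dtype=bool)
        return df
    if family == "module":
        df["fdr_pair"] = df.groupby("module", sort=False)["p_pair"].transform(
            lambda s: bh_adjust(s.to_numpy())
        )
    elif family == "global":
        df["fdr_pair"] = bh_adjust(df["p_pair"].to_numpy())
    else:
        raise ValueError("family must be 'module' or 'global'")
    df["coexpressed"] = (df["r_pair"] < 0) & (df["fdr_pair"] < fdr_threshold)
    return df.sort_values(["module", "mirna", "gene"], key=lambda s: s.astype(str)).reset_index(
        drop=True
    )


def feature_trait_correlations(
    features_expr: ExpressionMatrix,
    phenotypes: PhenotypeTable,
    features: list[str] | None = None,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """(feature, trait, r, p, fdr) over shared samples; one BH family for all rows.

    Missing phenotype cells are excluded pairwise; constant traits are
    skipped with a warning.
    """
    feats = features if features is not None else features_expr.feature_ids
    shared = [s for s in features_expr.sample_ids if s in set(phenotypes.sample_ids)]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    expr = features_expr.subset_samples(shared)
    phen = phenotypes.values.loc[shared]
    rows = []
    for feat in feats:
        x = expr.values.loc[feat].to_numpy(dtype=float)
        for trait in phenotypes.trait_names:
            t = phen[trait].to_numpy(dtype=float)
            ok = ~np.isnan(t)
            if ok.sum() < 3:
                continue
            if np.std(t[ok]) == 0:
                logger.warning("trait %s is constant; skipped", trait)
                continue
            r, p = correlation_with_p(x, t)
            rows.append({"feature": feat, "trait": trait, "r": r, "p": p})
    df = pd.DataFrame.from_records(rows, columns=["feature", "trait", "r", "p"])
    if df.empty:
        df["fdr"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
        return df
    df["fdr"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = df["fdr"] < fdr_threshold
    return df


def build_triples(
    pairs: pd.DataFrame,
    mirna_trait: pd.DataFrame,
    gene_trait: pd.DataFrame,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Three-way records for co-expressed pairs whose members both correlate
    significantly with the same trait.

    Output rows are sorted by (module, mirna, gene, trait) and satisfy
    r_pair < 0, fdr_pair < threshold and both trait FDRs < threshold by
    construction.
    """
    co = pairs[pairs["coexpressed"]] if "coexpressed" in pairs.columns else pairs
    mt = mirna_trait[mirna_trait["fdr"] < fdr_threshold]
    gt = gene_trait[gene_trait["fdr"] < fdr_threshold]
    mt_idx = {(f, normalize_trait_label(t)): (r, q) for f, t, r, q in zip(mt["feature"], mt["trait"], mt["r"], mt["fdr"])}
    gt_idx = {(f, normalize_trait_label(t)): (r, q) for f, t, r, q in zip(gt["feature"], gt["trait"], gt["r"], gt["fdr"])}
    trait_labels = {normalize_trait_label(t): t for t in mirna_trait["trait"].unique()}
    rows = []
    for rec in co.itertuples(index=False):
        for norm, label in trait_labels.items():
            m_hit = mt_idx.get((rec.mirna, norm))
            g_hit = gt_idx.get((rec.gene, norm))
            if m_hit is None or g_hit is None:
                continue
            rows.append(
                {
                    "module": rec.module,
                    "mirna": rec.mirna,
                    "gene": rec.gene,
                    "context_percentile": rec.context_percentile,
                    "r_pair": rec.r_pair,
                    "fdr_pair": rec.fdr_pair,
                    "trait": label,
                    "r_mirna_trait": m_hit[0],
                    "fdr_mirna_trait": m_hit[1],
                    "r_gene_trait": g_hit[0],
                    "fdr_gene_trait": g_hit[1],
                }
            )
    df = pd.DataFrame.from_records(rows, columns=TRIPLE_COLUMNS)
    return df.sort_values(["module", "mirna", "gene", "trait"], key=lambda s: s.astype(str)).reset_index(
        drop=True
    )


def count_triples(triples: pd.DataFrame, by: str = "module") -> pd.Series:
    """Distinct (mirna, gene) pairs per module or per (normalised) trait."""
    if by == "module":
        key = triples["module"]
    elif by == "trait":
        key = triples["trait"].map(normalize_trait_label)
    else:
        raise ValueError("grouping key must be 'module' or 'trait'")
    if triples.empty:
        return pd.Series(dtype=int)
    return (
        triples.assign(_key=key)
        .groupby("_key")
        .apply(lambda g: g[["mirna", "gene"]].drop_duplicates().shape[0], include_groups=False)
        .astype(int)
    )


def min_fdr_pair(table: pd.DataFrame, module) -> tuple[str, str, float]:
    """(mirna, gene, fdr) of the most significant pair in a module."""
    sub = table[table["module"] == module]
    if sub.empty:
        raise ValueError(f"module {module!r} not present")
    sub = sub.drop_duplicates(subset=["mirna", "gene"])
    sub = sub.sort_values(["fdr_pair", "mirna", "gene"])
    row = sub.iloc[0]
    return str(row["mirna"]), str(row["gene"]), float(row["fdr_pair"])
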