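"""Count normalisation and per-condition matrix preparation.

Raw miRNA counts are normalised with median-of-ratios size factors (the
standard count-normalisation used for RNA-seq), log2-transformed with a
pseudocount, and split into one matrix per dietary condition.  Low-expression
features are removed with configurable thresholds applied in every condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import ConditionMap, ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class SizeFactors:
    """Per-sample positive scale factors with geometric mean 1."""

    factors: pd.Series

    def __post_init__(self) -> None:
        vals = self.factors.to_numpy(dtype=float)
        if (vals <= 0).any():
            raise ValueError("size factors must be positive")
        gm = np.exp(np.mean(np.log(vals)))
        if abs(gm - 1.0) > 1e-9:
            raise ValueError(f"size factors must have geometric mean 1 (got {gm})")

    def __getitem__(self, sample: str) -> float:
        return float(self.factors[sample])


@dataclass
class MultiConditionExpression:
    """One expression matrix per condition over a shared, identically ordered feature set."""

    matrices: dict[str, ExpressionMatrix]

    def __post_init__(self) -> None:
        if not self.matrices:
            raise ValueError("no conditions")
        feats = None
        seen_samples: set[str] = set()
        for cond, m in self.matrices.items():
            if feats is None:
                feats = m.feature_ids
            elif m.feature_ids != feats:
                raise ValueError(f"condition {cond!r} has a different feature list")
            overlap = seen_samples.intersection(m.sample_ids)
            if overlap:
                raise ValueError(f"samples appear in more than one condition: {sorted(overlap)}")
            seen_samples.update(m.sample_ids)

    @property
    def conditions(self) -> list[str]:
        return list(self.matrices)

    @property
    def feature_ids(self) -> list[str]:
        return next(iter(self.matrices.values())).feature_ids

    def __getitem__(self, condition: str) -> ExpressionMatrix:
        return self.matrices[condition]

    def items(self):
        return self.matrices.items()


def median_of_ratios(counts: ExpressionMatrix) -> SizeFactors:
    """Median-of-ratios size factors.

    The reference is the per-feature geometric mean over samples, computed on
    features with no zero count; each sample's factor is the median ratio of
    its counts to the reference, rescaled so factors have geometric mean 1.
    """
    if counts.scale != "counts":
        raise ValueError("size factors are computed from counts-scale matrices")
    mat = counts.values.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature has all-positive counts; consider adding a pseudocount "
            "before computing size factors"
        )
    sub = mat[positive]
    log_ref = np.mean(np.log(sub), axis=1)
    ratios = np.log(sub) - log_ref[:, None]
    log_factors = np.median(ratios, axis=0)
    log_factors = log_factors - np.mean(log_factors)  # geometric mean 1
    return SizeFactors(pd.Series(np.exp(log_factors), index=counts.sample_ids))


def normalize_log(
    counts: ExpressionMatrix, factors: SizeFactors, pseudocount: float = 1.0
) -> ExpressionMatrix:
    """log2(count / size_factor + pseudocount)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    missing = [s for s in counts.sample_ids if s not in factors.factors.index]
    if missing:
        raise ValueError(f"no size factor for samples: {missing}")
    f = factors.factors[counts.sample_ids].to_numpy(dtype=float)
    vals = np.log2(counts.values.to_numpy(dtype=float) / f[None, :] + pseudocount)
    df = pd.DataFrame(vals, index=counts.feature_ids, columns=counts.sample_ids)
    return ExpressionMatrix(df, scale="log_normalized")


def split_by_condition(
    expr: ExpressionMatrix, condition_map: ConditionMap
) -> dict[str, ExpressionMatrix]:
    """Split columns into per-condition matrices, preserving feature order."""
    unmapped = [s for s in expr.sample_ids if s not in condition_map.mapping]
    if unmapped:
        raise ValueError(f"samples not mapped to a condition: {unmapped}")
    out: dict[str, ExpressionMatrix] = {}
    for cond in condition_map.conditions:
        samples = [s for s in expr.sample_ids if condition_map.mapping[s] == cond]
        if not samples:
            raise ValueError(f"condition {cond!r} has no samples in the matrix")
        out[cond] = expr.subset_samples(samples)
    return out


def filter_features(
    counts_by_condition: dict[str, ExpressionMatrix],
    min_mean_count: float = 1.0,
    min_fraction_nonzero: float = 0.25,
    size_factors: dict[str, SizeFactors] | None = None,
) -> dict[str, ExpressionMatrix]:
    """Keep features passing both thresholds in EVERY condition.

    ``min_mean_count`` applies to the per-condition mean of (optionally
    size-factor-normalised) counts; ``min_fraction_nonzero`` to the fraction
    of samples with a non-zero count.  Feature order is preserved.
    """
    feats = None
    keep = None
    for cond, m in counts_by_condition.items():
        if feats is None:
            feats = m.feature_ids
            keep = np.ones(len(feats), dtype=bool)
        elif m.feature_ids != feats:
            raise ValueError("feature lists differ across conditions")
        vals = m.values.to_numpy(dtype=float)
        if size_factors is not None:
            f = size_factors[cond].factors[m.sample_ids].to_numpy(dtype=float)
            norm = vals / f[None, :]
        else:
            norm = vals
        keep &= norm.mean(axis=1) >= min_mean_count
        keep &= (vals > 0).mean(axis=1) >= min_fraction_nonzero
    retained = [f for f, k in zip(feats, keep) if k]
    if not retained:
        raise ValueError("no features pass the expression filters")
    logger.info("feature filter retained %d of %d features", len(retained), len(feats))
    return {cond: m.subset_features(retained) for cond, m in counts_by_condition.items()}


def preprocess(
    counts: ExpressionMatrix,
    condition_map: ConditionMap,
    min_mean_count: float = 1.0,
    min_fraction_nonzero: float = 0.25,
    pseudocount: float = 1.0,
    per_condition_factors: bool = True,
) -> tuple[MultiConditionExpression, dict[str, SizeFactors]]:
    """Full preprocessing: split, size factors, filter, log-normalise.

    Size factors are computed per condition by default so each condition
    enters the consensus analysis as an independently normalised data set; a
    joint normalisation over all samples is available via
    ``per_condition_factors=False``.
    """
    condition_map.validate_against(counts)
    by_cond = split_by_condition(counts, condition_map)
    if per_condition_factors:
        factors = {cond: median_of_ratios(m) for cond, m in by_cond.items()}
    else:
        joint = median_of_ratios(counts)
        factors = {
            cond: SizeFactors(_renorm(joint.factors[m.sample_ids]))
            for cond, m in by_cond.items()
        }
    filtered = filter_features(
        by_cond, min_mean_count, min_fraction_nonzero, size_factors=factors
    )
    matrices = {
        cond: normalize_log(m, factors[cond], pseudocount)
        for cond, m in filtered.items()
    }
    return MultiConditionExpression(matrices), factors


def _renorm(factors: pd.Series) -> pd.Series:
    logf = np.log(factors.to_numpy(dtype=float))
    return pd.Series(np.exp(logf - logf.mean()), index=factors.index)
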