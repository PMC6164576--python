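"""Module eigengenes, eigengene-based connectivity (k.ME) and module-trait statistics.

The eigengene of a module is the first principal component of its
standardised member expression and serves as the module's representative
profile.  k.ME is the Pearson correlation of a feature with its module
eigengene; features with k.ME > 0.6 are treated as representative module
members, and modules are selected when an eigengene-trait correlation
satisfies |r| > 0.5 and p < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ConditionMap, ExpressionMatrix, PhenotypeTable

logger = logging.getLogger(__name__)

_P_FLOOR = 1e-300


@dataclass
class Eigengene:
    """First principal component of a module's standardised expression."""

    module: object
    condition: str
    sample_ids: list[str]
    values: np.ndarray  # unit variance
    variance_explained: float

    @property
    def series(self) -> pd.Series:
        return pd.Series(self.values, index=self.sample_ids)


def _standardize_rows(mat: np.ndarray) -> np.ndarray:
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=1, keepdims=True)
    return (mat - mean) / sd


def module_eigengene(
    expr: ExpressionMatrix, members: list[str], module=None, condition: str = ""
) -> Eigengene:
    """Eigengene of ``members`` within one condition's expression matrix.

    Members are standardised to mean 0 / variance 1 across samples; the
    eigengene is the first right singular vector of the member x sample
    matrix, rescaled to unit variance and oriented so it correlates
    non-negatively with the mean standardised member profile.
    """
    if len(members) < 2:
        raise ValueError("a module eigengene needs at least 2 members")
    sub = expr.values.loc[list(members)].to_numpy(dtype=float)
    if sub.shape[1] < 3:
        raise ValueError("a module eigengene needs at least 3 samples")
    sds = sub.std(axis=1, ddof=1)
    usable = sds > 0
    if not usable.all():
        dropped = [m for m, u in zip(members, usable) if not u]
        logger.warning("excluding zero-variance members from eigengene: %s", dropped)
        sub = sub[usable]
        if sub.shape[0] < 2:
            raise ValueError("fewer than 2 members with non-zero variance")
    z = _standardize_rows(sub)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    pc = vt[0]
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    mean_profile = z.mean(axis=0)
    if np.dot(pc, mean_profile) < 0:
        pc = -pc
    pc = pc / pc.std(ddof=1)
    return Eigengene(
        module=module,
        condition=condition,
        sample_ids=expr.sample_ids,
        values=pc,
        variance_explained=var_explained,
    )


def correlation_with_p(x, y) -> tuple[float, float]:
    """Pearson r with a two-sided p from the t transform on n-2 df.

    p is floored at 1e-300 so perfect correlations do not underflow to 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired non-missing values")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise ValueError("undefined correlation: constant vector")
    r = float(np.corrcoef(x, y)[0, 1])
    r = min(1.0, max(-1.0, r))
    if abs(r) >= 1.0:
        return r, _P_FLOOR
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(max(p, _P_FLOOR))


def condition_eigengenes(expr_by_condition, assignment) -> dict[tuple[str, object], Eigengene]:
    """Eigengene per (condition, non-grey module)."""
    out: dict[tuple[str, object], Eigengene] = {}
    for cond, expr in expr_by_condition.items():
        for module, members in assignment.modules.items():
            out[(cond, module)] = module_eigengene(
                expr, members, module=module, condition=cond
            )
    return out


def compute_kme(expr_by_condition, assignment) -> pd.DataFrame:
    """k.ME table: per-condition and pooled eigengene-based connectivity.

    The pooled column correlates each feature's within-condition standardised
    expression, concatenated over conditions, with the concatenation of the
    per-condition eigengenes of its module.
    """
    eigengenes = condition_eigengenes(expr_by_condition, assignment)
    conditions = list(expr_by_condition)
    records = []
    for module, members in assignment.modules.items():
        pooled_eig = np.concatenate(
            [eigengenes[(c, module)].values for c in conditions]
        )
        for mirna in members:
            rec: dict[str, object] = {"mirna": mirna, "module": module}
            pooled_expr = []
            for cond in conditions:
                expr = expr_by_condition[cond]
                x = expr.values.loc[mirna].to_numpy(dtype=float)
                r, p = correlation_with_p(x, eigengenes[(cond, module)].values)
                rec[f"kme_{cond}"] = r
                rec[f"p_kme_{cond}"] = p
                pooled_expr.append((x - x.mean()) / x.std(ddof=1))
            r_all, p_all = correlation_with_p(np.concatenate(pooled_expr), pooled_eig)
            rec["kme_all"] = r_all
            rec["p_kme_all"] = p_all
            records.append(rec)
    cols = ["mirna", "module", "kme_all", "p_kme_all"]
    for cond in conditions:
        cols += [f"kme_{cond}", f"p_kme_{cond}"]
    return pd.DataFrame.from_records(records)[cols]


def select_module_members(kme_table: pd.DataFrame, threshold: float = 0.6) -> pd.DataFrame:
    """Rows with pooled k.ME strictly above ``threshold``.

    The inequality is strict; values printed at 2-decimal precision that
    round to exactly the threshold are excluded by this rule.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    return kme_table[kme_table["kme_all"] > threshold].reset_index(drop=True)


def hub_mirna(kme_table: pd.DataFrame, module) -> str:
    """Member with the highest pooled k.ME; ties broken lexicographically."""
    sub = kme_table[kme_table["module"] == module]
    if sub.empty:
        raise ValueError(f"module {module!r} has no members in the k.ME table")
    sub = sub.sort_values(["kme_all", "mirna"], ascending=[False, True])
    return str(sub.iloc[0]["mirna"])


@dataclass
class ModuleTraitMatrix:
    """Per-condition module x trait correlation (r), p-value and selection flags."""

    r: dict[str, pd.DataFrame]
    p: dict[str, pd.DataFrame]
    flagged: dict[str, pd.DataFrame]

    @property
    def conditions(self) -> list[str]:
        return list(self.r)


def module_trait_relationships(
    eigengenes: dict[tuple[str, object], Eigengene],
    phenotypes: PhenotypeTable,
    condition_map: ConditionMap,
    r_threshold: float = 0.5,
    p_threshold: float = 0.05,
) -> ModuleTraitMatrix:
    """Pearson eigengene-trait correlations with pairwise missing-data exclusion.

    A cell is flagged when |r| > ``r_threshold`` AND p < ``p_threshold``
    (both strict, matching the module selection rule).
    """
    conditions = sorted({c for c, _ in eigengenes})
    modules = sorted({m for _, m in eigengenes}, key=str)
    traits = phenotypes.trait_names
    r_out, p_out, f_out = {}, {}, {}
    for cond in conditions:
        r_mat = pd.DataFrame(np.nan, index=modules, columns=traits)
        p_mat = pd.DataFrame(np.nan, index=modules, columns=traits)
        for module in modules:
            eig = eigengenes[(cond, module)]
            eig_series = eig.series
            shared = [s for s in eig.sample_ids if s in phenotypes.values.index]
            for trait in traits:
                t_vals = phenotypes.values.loc[shared, trait].to_numpy(dtype=float)
                e_vals = eig_series[shared].to_numpy(dtype=float)
                ok = ~np.isnan(t_vals)
                if ok.sum() < 3:
                    logger.warning(
                        "trait %s in condition %s: fewer than 3 values; skipped",
                        trait,
                        cond,
                    )
                    continue
                if np.std(t_vals[ok]) == 0:
                    logger.warning(
                        "trait %s constant in condition %s; correlation undefined",
                        trait,
                        cond,
                    )
                    continue
                r, p = correlation_with_p(e_vals, t_vals)
                r_mat.loc[module, trait] = r
                p_mat.loc[module, trait] = p
        r_out[cond] = r_mat
        p_out[cond] = p_mat
        f_out[cond] = (r_mat.abs() > r_threshold) & (p_mat < p_threshold)
    return ModuleTraitMatrix(r=r_out, p=p_out, flagged=f_out)


def select_modules(mt: ModuleTraitMatrix) -> list:
    """Modules with at least one flagged module-trait cell in any condition."""
    selected = []
    for cond in mt.conditions:
        flags = mt.flagged[cond]
        for module in flags.index:
            if bool(flags.loc[module].any()) and module not in selected:
                selected.append(module)
    return selected
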