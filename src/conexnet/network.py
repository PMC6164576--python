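"""Signed weighted co-expression networks, consensus topological overlap and
module detection.

Per condition, pairwise Pearson correlation is mapped to a signed similarity
s_ij = (1 + r_ij)/2, raised to a soft-thresholding power beta to give a
weighted adjacency, and converted to a topological overlap measure (TOM)
that augments direct adjacency with shared-neighbour strength.  The
consensus TOM across conditions (after quantile calibration, element-wise
minimum by default) is clustered with average linkage on 1 - TOM, modules
are extracted with a height-based dynamic branch cut subject to a minimum
size, and modules with highly correlated eigengenes in every condition are
merged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .core_io import ExpressionMatrix
from .module_trait import module_eigengene

logger = logging.getLogger(__name__)

#: Standard colour names assigned to modules in decreasing size order.
MODULE_COLORS = (
    "turquoise",
    "blue",
    "brown",
    "yellow",
    "green",
    "red",
    "black",
    "pink",
    "magenta",
    "purple",
)

GREY = "grey"

#: deep-split sensitivity -> fraction of the maximum merge height at which
#: branches are cut.  TOM dissimilarities are strongly compressed toward the
#: top of the tree, so branch structure lives in the top few percent of the
#: height range; higher sensitivity cuts closer to the top and exposes more
#: branches, which the recursive re-split then subdivides.
DEEP_SPLIT_HEIGHT = {0: 0.96, 1: 0.97, 2: 0.975, 3: 0.98, 4: 0.985}


@dataclass
class NetworkParams:
    """Parameters of the consensus network construction."""

    beta: float = 9.0
    min_module_size: int = 20
    deep_split: int = 2
    merge_cut_height: float = 0.25
    consensus_quantile: float = 0.0
    calibration_quantile: float = 0.95
    #: pooled eigengene-connectivity needed to (re)assign a feature to a
    #: module during refinement; 0.4 is roughly the 1% two-sided
    #: significance point of a Pearson correlation at 36 samples.
    kme_assign_threshold: float = 0.4
    #: optional quality control: when > 0, a module whose eigengene explains
    #: less than this fraction of member variance in some condition is
    #: dissolved to grey.  Off by default: on data where most features are
    #: co-regulated, normalisation residuals can dilute a genuine module's
    #: variance explained into the same range as artefactual clusters, so a
    #: hard gate removes real modules about as often as artefacts.
    min_module_varexp: float = 0.0
    refine_iterations: int = 5

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not 0 < self.merge_cut_height < 1:
            raise ValueError("merge_cut_height must be in (0, 1)")
        if not 0 <= self.consensus_quantile <= 0.5:
            raise ValueError("consensus_quantile must be in [0, 0.5]")
        if self.deep_split not in DEEP_SPLIT_HEIGHT:
            raise ValueError("deep_split must be one of 0..4")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")


@dataclass
class LabeledMatrix:
    """A symmetric feature x feature matrix with aligned ids."""

    feature_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.feature_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match feature ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("matrix is not symmetric within 1e-10")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.feature_ids)


@dataclass
class Dendrogram:
    """Average-linkage merge history over features (scipy linkage encoding)."""

    feature_ids: list[str]
    linkage: np.ndarray

    def __post_init__(self) -> None:
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-12):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def max_height(self) -> float:
        return float(self.linkage[-1, 2]) if len(self.linkage) else 0.0


@dataclass
class ModuleAssignment:
    """Feature -> module label; ``grey`` marks unassigned features."""

    labels: pd.Series  # index = feature ids, values = module labels (str)
    color_order: list[str] = field(default_factory=list)

    @property
    def modules(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for color in self.color_order:
            out[color] = list(self.labels.index[self.labels == color])
        return out

    @property
    def module_sizes(self) -> dict[str, int]:
        return {m: len(v) for m, v in self.modules.items()}

    @property
    def grey_fraction(self) -> float:
        return float((self.labels == GREY).mean())

    def as_int_labels(self) -> pd.Series:
        """grey -> 0, modules -> 1..k in decreasing size order."""
        mapping = {GREY: 0}
        mapping.update({c: i + 1 for i, c in enumerate(self.color_order)})
        return self.labels.map(mapping)


# ---------------------------------------------------------------------------
# matrix stages
# ---------------------------------------------------------------------------


def signed_similarity(expr: ExpressionMatrix) -> LabeledMatrix:
    """s_ij = (1 + cor(x_i, x_j)) / 2 with Pearson correlation."""
    mat = expr.values.to_numpy(dtype=float)
    if mat.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    sds = mat.std(axis=1, ddof=1)
    if (sds == 0).any():
        bad = [f for f, s in zip(expr.feature_ids, sds) if s == 0]
        raise ValueError(f"zero-variance features: {bad}")
    corr = np.corrcoef(mat)
    sim = (1.0 + corr) / 2.0
    np.clip(sim, 0.0, 1.0, out=sim)
    np.fill_diagonal(sim, 1.0)
    sim = (sim + sim.T) / 2.0
    return LabeledMatrix(expr.feature_ids, sim)


def soft_adjacency(sim: LabeledMatrix, beta: float = 9.0) -> LabeledMatrix:
    """a_ij = s_ij ** beta off-diagonal; the diagonal is 0 for connectivity sums."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    adj = np.power(sim.values, beta)
    np.fill_diagonal(adj, 0.0)
    return LabeledMatrix(sim.feature_ids, adj)


def topological_overlap(adj: LabeledMatrix) -> LabeledMatrix:
    """TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij), diagonal 1.

    l_ij sums shared-neighbour adjacency a_iu * a_uj over u distinct from
    both i and j, and k_i is the connectivity of node i.
    """
    a = adj.values.copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a  # includes no i/j terms because the diagonal is zero
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a) / denom
    tom[~np.isfinite(tom)] = 0.0
    np.fill_diagonal(tom, 1.0)
    tom = (tom + tom.T) / 2.0
    np.clip(tom, 0.0, 1.0, out=tom)
    return LabeledMatrix(adj.feature_ids, tom)


def consensus_tom(
    toms: list[LabeledMatrix],
    quantile: float = 0.0,
    calibrate: bool = True,
    calibration_quantile: float = 0.95,
) -> LabeledMatrix:
    """Consensus of per-condition TOM matrices.

    Each matrix is first scaled so the ``calibration_quantile`` of its
    off-diagonal entries matches that of the first matrix (entries capped at
    1); the consensus entry is the ``quantile``-quantile across matrices
    (0 = element-wise minimum).
    """
    if len(toms) < 2:
        raise ValueError("need at least 2 matrices for a consensus")
    ids = toms[0].feature_ids
    for t in toms[1:]:
        if t.feature_ids != ids:
            raise ValueError("feature sets differ across TOM matrices")
    n = len(ids)
    off = ~np.eye(n, dtype=bool)
    mats = [t.values.copy() for t in toms]
    if calibrate:
        ref = np.quantile(mats[0][off], calibration_quantile)
        for m in mats[1:]:
            q = np.quantile(m[off], calibration_quantile)
            if q > 0:
                m *= ref / q
            np.clip(m, 0.0, 1.0, out=m)
    stack = np.stack(mats)
    cons = np.quantile(stack, quantile, axis=0)
    np.fill_diagonal(cons, 1.0)
    cons = (cons + cons.T) / 2.0
    return LabeledMatrix(ids, cons)


# ---------------------------------------------------------------------------
# clustering and tree cut
# ---------------------------------------------------------------------------


def cluster_features(tom: LabeledMatrix) -> Dendrogram:
    """Average-linkage clustering on dissimilarity 1 - TOM.

    Features are processed in lexicographic id order so the merge history is
    independent of the input ordering.
    """
    order = sorted(range(len(tom.feature_ids)), key=lambda i: tom.feature_ids[i])
    ids = [tom.feature_ids[i] for i in order]
    d = 1.0 - tom.values[np.ix_(order, order)]
    np.fill_diagonal(d, 0.0)
    condensed = d[np.triu_indices_from(d, k=1)]
    z = hierarchy.linkage(condensed, method="average")
    return Dendrogram(feature_ids=ids, linkage=z)


def _branches_below(node: hierarchy.ClusterNode, threshold: float) -> list[hierarchy.ClusterNode]:
    """Maximal subtrees whose top merge height is below ``threshold``."""
    out: list[hierarchy.ClusterNode] = []
    stack = [node]
    while stack:
        nd = stack.pop()
        if nd.is_leaf() or nd.dist < threshold:
            out.append(nd)
        else:
            stack.extend([nd.left, nd.right])
    return out


def _cut_recursive(
    node: hierarchy.ClusterNode, frac: float, min_size: int
) -> list[list[int]]:
    """Cut the subtree at ``frac`` of its own top height; recurse into large branches.

    A split is accepted only when it produces at least two branches of
    ``min_size`` or more; otherwise the subtree is kept whole.  Sub-minimum
    side branches produced by an accepted split are returned as their own
    (small) groups and end up grey.
    """
    leaves = node.pre_order(lambda nd: nd.id)
    if node.is_leaf() or len(leaves) < 2 * min_size or node.dist <= 0:
        return [leaves]
    threshold = frac * node.dist
    branches = _branches_below(node, threshold)
    big = [b for b in branches if b.get_count() >= min_size]
    if len(big) < 2:
        return [leaves]
    groups: list[list[int]] = []
    for b in branches:
        if b.get_count() >= min_size:
            groups.extend(_cut_recursive(b, frac, min_size))
        else:
            groups.append(b.pre_order(lambda nd: nd.id))
    return groups


def dynamic_tree_cut(
    dendrogram: Dendrogram, min_module_size: int = 20, deep_split: int = 2
) -> ModuleAssignment:
    """Height-based dynamic branch cut (tree variant).

    The dendrogram is cut at a deep-split-dependent fraction of the maximum
    merge height (0..4 -> 0.99, 0.97, 0.95, 0.93, 0.91); branches of at
    least ``min_module_size`` features become modules and are recursively
    re-cut where their internal structure supports further large
    sub-branches.  Smaller branches are grey.  Modules are labelled by
    decreasing size using the conventional colour order.
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    if deep_split not in DEEP_SPLIT_HEIGHT:
        raise ValueError("deep_split must be one of 0..4")
    ids = dendrogram.feature_ids
    n = len(ids)
    if len(dendrogram.linkage) == 0:
        return ModuleAssignment(pd.Series([GREY] * n, index=ids), [])
    root = hierarchy.to_tree(dendrogram.linkage)
    frac = DEEP_SPLIT_HEIGHT[deep_split]
    threshold = frac * dendrogram.max_height
    branches = _branches_below(root, threshold)
    groups: list[list[int]] = []
    for b in branches:
        if b.get_count() >= min_module_size:
            groups.extend(_cut_recursive(b, frac, min_module_size))
        else:
            groups.append(b.pre_order(lambda nd: nd.id))
    module_groups = [g for g in groups if len(g) >= min_module_size]
    module_groups.sort(key=lambda g: (-len(g), min(ids[i] for i in g)))
    labels = pd.Series([GREY] * n, index=ids)
    colors: list[str] = []
    for rank, group in enumerate(module_groups):
        color = MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module{rank + 1}"
        colors.append(color)
        for i in group:
            labels.iloc[i] = color
    logger.info(
        "dynamic tree cut: %d modules %s, %d grey",
        len(colors),
        {c: int((labels == c).sum()) for c in colors},
        int((labels == GREY).sum()),
    )
    return ModuleAssignment(labels=labels, color_order=colors)


def _relabel_by_size(labels: pd.Series) -> ModuleAssignment:
    sizes = labels[labels != GREY].value_counts()
    ordered = sorted(sizes.index, key=lambda m: (-sizes[m], str(m)))
    mapping = {}
    colors = []
    for rank, old in enumerate(ordered):
        color = MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module{rank + 1}"
        mapping[old] = color
        colors.append(color)
    new = labels.map(lambda v: GREY if v == GREY else mapping[v])
    return ModuleAssignment(labels=new, color_order=colors)


def merge_close_modules(
    assignment: ModuleAssignment,
    expr_by_condition,
    merge_cut_height: float = 0.25,
) -> ModuleAssignment:
    """Merge modules whose eigengenes are close in every condition.

    Distance between two modules is max over conditions of
    1 - cor(eigengene_1, eigengene_2); the closest pair below
    ``merge_cut_height`` is merged first and distances are recomputed until
    no pair qualifies.
    """
    labels = assignment.labels.copy()
    while True:
        modules = [m for m in labels.unique() if m != GREY]
        if len(modules) < 2:
            break
        dist = {}
        for i, m1 in enumerate(sorted(modules, key=str)):
            for m2 in sorted(modules, key=str)[i + 1 :]:
                worst = 0.0
                for cond, expr in expr_by_condition.items():
                    e1 = module_eigengene(expr, list(labels.index[labels == m1]))
                    e2 = module_eigengene(expr, list(labels.index[labels == m2]))
                    r = float(np.corrcoef(e1.values, e2.values)[0, 1])
                    worst = max(worst, 1.0 - r)
                dist[(m1, m2)] = worst
        (m1, m2), d = min(dist.items(), key=lambda kv: (kv[1], str(kv[0])))
        if d >= merge_cut_height:
            break
        logger.info("merging modules %s and %s (consensus dissimilarity %.3f)", m1, m2, d)
        labels[labels == m2] = m1
    return _relabel_by_size(labels)


def _pooled_kme(labels: pd.Series, expr_by_condition) -> tuple[np.ndarray, list]:
    """Pooled eigengene connectivity of every feature to every current module."""
    conds = list(expr_by_condition)
    ids = list(labels.index)
    modules = sorted({m for m in labels.unique() if m != GREY}, key=str)
    pooled = []
    eig: dict[object, list[np.ndarray]] = {m: [] for m in modules}
    for cond in conds:
        # align rows with the label index (may differ from matrix row order)
        vals = expr_by_condition[cond].values.loc[ids].to_numpy(dtype=float)
        z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(
            axis=1, ddof=1, keepdims=True
        )
        pooled.append(z)
        for m in modules:
            members = list(labels.index[labels == m])
            eig[m].append(
                module_eigengene(expr_by_condition[cond], members).values
            )
    z_all = np.hstack(pooled)
    z_all = (z_all - z_all.mean(axis=1, keepdims=True)) / z_all.std(
        axis=1, ddof=1, keepdims=True
    )
    kme = np.zeros((len(ids), len(modules)))
    for j, m in enumerate(modules):
        e = np.concatenate(eig[m])
        e = (e - e.mean()) / e.std(ddof=1)
        kme[:, j] = z_all @ e / (z_all.shape[1] - 1)
    return kme, modules


def refine_modules_by_kme(
    assignment: ModuleAssignment,
    expr_by_condition,
    kme_threshold: float = 0.4,
    min_module_size: int = 20,
    n_iter: int = 5,
) -> ModuleAssignment:
    """Reassign features by pooled eigengene connectivity.

    Every feature joins the module whose eigengene it correlates with most
    (pooled over conditions) when that connectivity exceeds the threshold,
    and is grey otherwise; modules falling below the minimum size dissolve.
    Iterates to a fixed point.  This is the consensus analogue of the
    kME-based gene reassignment applied after the tree cut in blockwise
    consensus workflows.
    """
    labels = assignment.labels.copy()
    for _ in range(n_iter):
        if not [m for m in labels.unique() if m != GREY]:
            break
        kme, modules = _pooled_kme(labels, expr_by_condition)
        mod_arr = np.asarray(modules, dtype=object)
        best = kme.argmax(axis=1)
        best_val = kme.max(axis=1)
        new = pd.Series(
            np.where(best_val > kme_threshold, mod_arr[best], GREY),
            index=labels.index,
        )
        for m in modules:
            if int((new == m).sum()) < min_module_size:
                new[new == m] = GREY
        if new.equals(labels):
            break
        labels = new
    return _relabel_by_size(labels)


def dissolve_weak_modules(
    assignment: ModuleAssignment,
    expr_by_condition,
    min_varexp: float = 1.0 / 3.0,
) -> ModuleAssignment:
    """Dissolve modules whose eigengene is a poor summary of its members.

    A genuine co-expression module is dominated by one latent profile, so
    its eigengene explains a sizeable share of member variance in every
    condition.  Clusters that owe their coherence to weak systematic
    artefacts (for example compositional residuals of count normalisation)
    fall well short of this; they are returned to grey.
    """
    labels = assignment.labels.copy()
    while True:
        modules = [m for m in labels.unique() if m != GREY]
        if not modules:
            break
        weak = []
        for m in sorted(modules, key=str):
            members = list(labels.index[labels == m])
            varexp = min(
                module_eigengene(expr, members).variance_explained
                for expr in expr_by_condition.values()
            )
            if varexp < min_varexp:
                weak.append((varexp, str(m), m))
        if not weak:
            break
        _, _, worst = min(weak)
        logger.info("dissolving low-coherence module %s", worst)
        labels[labels == worst] = GREY
    return _relabel_by_size(labels)


def detect_consensus_modules(
    expr_by_condition, params: NetworkParams | None = None
) -> tuple[ModuleAssignment, Dendrogram, LabeledMatrix]:
    """Full consensus-module pipeline over per-condition log expression.

    signed similarity -> soft adjacency -> TOM per condition -> consensus
    TOM -> average-linkage dendrogram -> dynamic branch cut -> eigengene
    merge -> kME refinement with a coherence check -> final eigengene merge.
    """
    params = params or NetworkParams()
    conditions = list(expr_by_condition)
    if len(conditions) < 2:
        raise ValueError("consensus modules need at least 2 conditions")
    toms = []
    for cond in conditions:
        sim = signed_similarity(expr_by_condition[cond])
        adj = soft_adjacency(sim, params.beta)
        toms.append(topological_overlap(adj))
    cons = consensus_tom(
        toms,
        quantile=params.consensus_quantile,
        calibration_quantile=params.calibration_quantile,
    )
    dendro = cluster_features(cons)
    assignment = dynamic_tree_cut(dendro, params.min_module_size, params.deep_split)
    if assignment.color_order:
        assignment = merge_close_modules(
            assignment, expr_by_condition, params.merge_cut_height
        )
        for _ in range(params.refine_iterations):
            refined = refine_modules_by_kme(
                assignment,
                expr_by_condition,
                kme_threshold=params.kme_assign_threshold,
                min_module_size=params.min_module_size,
                n_iter=params.refine_iterations,
            )
            if params.min_module_varexp > 0:
                refined = dissolve_weak_modules(
                    refined, expr_by_condition, params.min_module_varexp
                )
            if refined.labels.equals(assignment.labels):
                assignment = refined
                break
            assignment = refined
    if assignment.color_order:
        assignment = merge_close_modules(
            assignment, expr_by_condition, params.merge_cut_height
        )
    logger.info("consensus modules: %s", assignment.module_sizes)
    return assignment, dendro, cons
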