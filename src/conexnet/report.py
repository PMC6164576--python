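"""Pipeline orchestration: configuration, end-to-end runs and fixture checks.

``run_pipeline`` wires preprocessing, consensus network construction,
module-trait statistics, target integration and (optionally) enrichment into
one deterministic run that writes every artefact as TSV plus a JSON run
report.  ``verify_fixtures`` recomputes every number derivable from the
packaged reference tables and reports pass/fail per check.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import core_io, enrichment, integration, module_trait, preprocessing
from .core_io import ExpressionMatrix
from .network import NetworkParams, detect_consensus_modules

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable parameters plus input/output paths.

    Defaults mirror the reference analysis: soft power 9, minimum module
    size 20, deepSplit 2, mergeCutHeight 0.25, k.ME > 0.6, |r| > 0.5 with
    p < 0.05 for module-trait selection, context++ percentile >= 95 and
    FDR < 0.05 throughout.
    """

    counts_path: str = ""
    conditions_path: str = ""
    phenotypes_path: str = ""
    targets_path: str = ""
    mrna_path: str = ""
    gmt_path: str = ""
    out_dir: str = "conexnet_out"

    beta: float = 9.0
    min_module_size: int = 20
    deep_split: int = 2
    merge_cut_height: float = 0.25
    consensus_quantile: float = 0.0
    min_mean_count: float = 1.0
    min_fraction_nonzero: float = 0.25
    pseudocount: float = 1.0
    kme_threshold: float = 0.6
    module_trait_r: float = 0.5
    module_trait_p: float = 0.05
    percentile_cut: float = 95.0
    fdr: float = 0.05
    seed: int = 0

    def network_params(self) -> NetworkParams:
        return NetworkParams(
            beta=self.beta,
            min_module_size=self.min_module_size,
            deep_split=self.deep_split,
            merge_cut_height=self.merge_cut_height,
            consensus_quantile=self.consensus_quantile,
        )

    def to_toml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for key, value in asdict(self).items():
                if isinstance(value, str):
                    fh.write(f'{key} = "{value}"\n')
                else:
                    fh.write(f"{key} = {value}\n")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls(**data)


@dataclass
class RunReport:
    module_sizes: dict = field(default_factory=dict)
    selected_modules: list = field(default_factory=list)
    hub_mirnas: dict = field(default_factory=dict)
    n_targets_filtered: int = 0
    n_pairs_tested: int = 0
    n_pairs_coexpressed: int = 0
    n_triples: int = 0
    triples_per_trait: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def pooled_standardized(expr_by_condition) -> ExpressionMatrix:
    """Concatenate conditions after z-scoring each feature within condition.

    This is the pooled representation used for the all-sample k.ME column
    and the miRNA-mRNA / miRNA-trait correlations over the full sample set.
    """
    pieces = []
    for cond, expr in expr_by_condition.items():
        vals = expr.values.to_numpy(dtype=float)
        z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, ddof=1, keepdims=True)
        pieces.append(pd.DataFrame(z, index=expr.feature_ids, columns=expr.sample_ids))
    return ExpressionMatrix(pd.concat(pieces, axis=1), scale="log_normalized")


def run_pipeline_data(
    counts: ExpressionMatrix,
    condition_map: core_io.ConditionMap,
    phenotypes: core_io.PhenotypeTable,
    targets: core_io.TargetPredictionTable,
    mrna_expr: ExpressionMatrix,
    config: PipelineConfig | None = None,
    gene_sets: core_io.GeneSetCollection | None = None,
    out_dir: str | Path | None = None,
) -> tuple[RunReport, dict]:
    """Run every stage on in-memory inputs.

    Returns the run report plus a dict of intermediate artefacts
    (multi-condition expression, assignment, k.ME table, module-trait
    matrix, pairs, triples, enrichment tables).  When ``out_dir`` is given
    all tables are also written as TSV.
    """
    config = config or PipelineConfig()
    report = RunReport(config=asdict(config))
    artefacts: dict = {}
    t0 = time.perf_counter()

    mce, factors = preprocessing.preprocess(
        counts,
        condition_map,
        min_mean_count=config.min_mean_count,
        min_fraction_nonzero=config.min_fraction_nonzero,
        pseudocount=config.pseudocount,
    )
    artefacts["expression"] = mce
    artefacts["size_factors"] = factors
    report.stage_seconds["preprocess"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    assignment, dendro, cons = detect_consensus_modules(
        mce.matrices, config.network_params()
    )
    artefacts["assignment"] = assignment
    artefacts["dendrogram"] = dendro
    artefacts["consensus_tom"] = cons
    report.module_sizes = assignment.module_sizes
    report.stage_seconds["network"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    kme = module_trait.compute_kme(mce.matrices, assignment)
    members = module_trait.select_module_members(kme, config.kme_threshold)
    eigengenes = module_trait.condition_eigengenes(mce.matrices, assignment)
    mt = module_trait.module_trait_relationships(
        eigengenes,
        phenotypes,
        condition_map,
        r_threshold=config.module_trait_r,
        p_threshold=config.module_trait_p,
    )
    selected = module_trait.select_modules(mt)
    artefacts["kme"] = kme
    artefacts["members"] = members
    artefacts["module_trait"] = mt
    artefacts["selected_modules"] = selected
    report.selected_modules = [str(m) for m in selected]
    report.hub_mirnas = {
        str(m): module_trait.hub_mirna(kme, m) for m in assignment.color_order
    }
    report.stage_seconds["module_trait"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    filtered = integration.filter_targets(targets, config.percentile_cut)
    filtered = integration.restrict_to_expressed(filtered, mrna_expr)
    report.n_targets_filtered = len(filtered)
    pooled = pooled_standardized(mce.matrices)
    member_assignment = pd.Series(
        members["module"].to_numpy(), index=members["mirna"].to_numpy()
    )
    if selected:
        member_assignment = member_assignment[
            member_assignment.isin([m for m in selected])
        ]
    pairs = integration.pair_correlations(
        pooled, mrna_expr, filtered, member_assignment, fdr_threshold=config.fdr
    )
    mirna_trait = integration.feature_trait_correlations(
        pooled,
        phenotypes,
        features=sorted(set(pairs["mirna"])) if not pairs.empty else [],
        fdr_threshold=config.fdr,
    )
    gene_trait = integration.feature_trait_correlations(
        mrna_expr,
        phenotypes,
        features=sorted(set(pairs["gene"])) if not pairs.empty else [],
        fdr_threshold=config.fdr,
    )
    triples = integration.build_triples(pairs, mirna_trait, gene_trait, config.fdr)
    artefacts["pairs"] = pairs
    artefacts["mirna_trait"] = mirna_trait
    artefacts["gene_trait"] = gene_trait
    artefacts["triples"] = triples
    report.n_pairs_tested = len(pairs)
    report.n_pairs_coexpressed = int(pairs["coexpressed"].sum()) if not pairs.empty else 0
    report.n_triples = len(triples)
    counts_by_trait = integration.count_triples(triples, by="trait")
    report.triples_per_trait = {str(k): int(v) for k, v in counts_by_trait.items()}
    report.stage_seconds["integration"] = round(time.perf_counter() - t0, 3)

    if gene_sets is not None:
        t0 = time.perf_counter()
        universe = mrna_expr.feature_ids
        enr = {}
        for module in selected:
            query = sorted(
                set(
                    pairs[(pairs["module"] == module) & pairs["coexpressed"]]["gene"]
                )
            )
            if query:
                enr[str(module)] = enrichment.enrich(query, gene_sets, universe)
        artefacts["enrichment"] = enr
        report.stage_seconds["enrichment"] = round(time.perf_counter() - t0, 3)

    if out_dir is not None:
        _write_outputs(Path(out_dir), artefacts, report)
    return report, artefacts


def _write_outputs(out: Path, artefacts: dict, report: RunReport) -> None:
    out.mkdir(parents=True, exist_ok=True)
    assignment = artefacts["assignment"]
    assignment.labels.rename("module").to_frame().rename_axis("feature").to_csv(
        out / "modules.tsv", sep="\t"
    )
    pd.DataFrame(
        artefacts["dendrogram"].linkage, columns=["left", "right", "height", "count"]
    ).to_csv(out / "dendrogram.tsv", sep="\t", index=False, float_format="%.12g")
    artefacts["kme"].to_csv(out / "kme.tsv", sep="\t", index=False, float_format="%.12g")
    mt = artefacts["module_trait"]
    for cond in mt.conditions:
        mt.r[cond].rename_axis("module").to_csv(
            out / f"module_trait_r_{cond}.tsv", sep="\t", float_format="%.12g"
        )
        mt.p[cond].rename_axis("module").to_csv(
            out / f"module_trait_p_{cond}.tsv", sep="\t", float_format="%.12g"
        )
    artefacts["pairs"].to_csv(out / "pairs.tsv", sep="\t", index=False, float_format="%.12g")
    artefacts["triples"].to_csv(out / "triples.tsv", sep="\t", index=False, float_format="%.12g")
    for module, table in artefacts.get("enrichment", {}).items():
        table.to_csv(out / f"enrichment_{module}.tsv", sep="\t", index=False, float_format="%.12g")
    edges = [
        core_io.Edge(r.mirna, r.gene, -1, abs(r.r_pair), "mirna_gene")
        for r in artefacts["triples"].itertuples(index=False)
    ]
    core_io.write_network(edges, out / "network.sif", "sif")
    report.to_json(out / "report.json")


def run_pipeline(config: PipelineConfig) -> RunReport:
    """File-based entry point: read inputs named in the config, run, write."""
    for label, path in (
        ("counts", config.counts_path),
        ("conditions", config.conditions_path),
        ("phenotypes", config.phenotypes_path),
        ("targets", config.targets_path),
        ("mRNA", config.mrna_path),
    ):
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"{label} file not found: {path!r}")
    counts = core_io.read_expression(config.counts_path, scale="counts")
    cmap = core_io.read_condition_map(config.conditions_path)
    phen = core_io.read_phenotypes(config.phenotypes_path)
    targets = core_io.read_targets(config.targets_path)
    mrna = core_io.read_expression(config.mrna_path, scale="log_normalized")
    sets = core_io.read_gene_sets(config.gmt_path) if config.gmt_path else None
    report, _ = run_pipeline_data(
        counts, cmap, phen, targets, mrna, config=config, gene_sets=sets,
        out_dir=config.out_dir,
    )
    return report


# ---------------------------------------------------------------------------
# fixture verification
# ---------------------------------------------------------------------------


def verify_fixtures() -> pd.DataFrame:
    """Recompute every number derivable from the packaged reference tables.

    Returns one row per check: id, observed, expected, pass.
    """
    t2 = core_io.load_fixture("table2").table
    t6 = core_io.load_fixture("table6").table

    checks: list[tuple[str, object, object]] = []

    sizes2 = t2.groupby("module").size()
    checks.append(("table2_members_blue", int(sizes2.get("Blue", 0)), 18))
    checks.append(("table2_members_brown", int(sizes2.get("Brown", 0)), 12))
    checks.append(("table2_members_turquoise", int(sizes2.get("Turquoise", 0)), 19))

    hub = module_trait.hub_mirna(t2, "Blue")
    checks.append(("table2_hub_blue", hub, "bta-miR-30d"))
    checks.append(
        (
            "table2_hub_blue_kme",
            float(t2[t2["mirna"] == "bta-miR-30d"]["kme_all"].iloc[0]),
            0.93,
        )
    )
    checks.append(("table2_hub_brown", module_trait.hub_mirna(t2, "Brown"), "bta-miR-484"))
    checks.append(
        ("table2_hub_turquoise", module_trait.hub_mirna(t2, "Turquoise"), "bta-miR-16b")
    )

    by_module = integration.count_triples(t6, by="module")
    checks.append(("table6_pairs_blue", int(by_module.get("Blue", 0)), 68))
    checks.append(("table6_pairs_brown", int(by_module.get("Brown", 0)), 6))
    checks.append(("table6_pairs_turquoise", int(by_module.get("Turquoise", 0)), 2))

    by_trait = integration.count_triples(t6, by="trait")
    checks.append(("table6_pairs_milk_yield", int(by_trait.get("milk yield", 0)), 28))
    checks.append(("table6_pairs_protein_yield", int(by_trait.get("protein yield", 0)), 31))
    checks.append(
        ("table6_pairs_protein_percentage", int(by_trait.get("protein percentage", 0)), 5)
    )

    mirna_b, gene_b, fdr_b = integration.min_fdr_pair(t6, "Blue")
    checks.append(("table6_min_fdr_blue_pair", f"{mirna_b}/{gene_b}", "bta-miR-183/RHBDD2"))
    checks.append(("table6_min_fdr_blue", fdr_b, 0.003))
    mirna_r, gene_r, fdr_r = integration.min_fdr_pair(t6, "Brown")
    checks.append(("table6_min_fdr_brown_pair", f"{mirna_r}/{gene_r}", "bta-miR-484/EIF1AD"))
    checks.append(("table6_min_fdr_brown", fdr_r, 0.011))
    mirna_t, gene_t, fdr_t = integration.min_fdr_pair(t6, "Turquoise")
    checks.append(
        ("table6_min_fdr_turquoise_pair", f"{mirna_t}/{gene_t}", "bta-miR-130a/SBSPON")
    )
    checks.append(("table6_min_fdr_turquoise", fdr_t, 0.004))

    rows = []
    for check_id, observed, expected in checks:
        if isinstance(expected, float):
            ok = bool(np.isclose(observed, expected, rtol=0, atol=1e-9))
        else:
            ok = observed == expected
        rows.append(
            {"check": check_id, "observed": observed, "expected": expected, "pass": ok}
        )
    return pd.DataFrame.from_records(rows)
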