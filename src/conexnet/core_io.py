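"""Readers and writers for the tabular and graph formats used by the pipeline.

Expression matrices, phenotype tables, target-prediction tables and gene-set
collections are all plain TSV/CSV (tab is the default delimiter; comma is
auto-detected).  Network exports support SIF, GraphML and plain TSV edge
lists.  Curated reference tables (``table1``, ``table2``, ``table6``) are
packaged under ``data/fixtures`` and loaded with :func:`load_fixture`.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCALES = ("counts", "log_normalized")

#: Fixture names available to :func:`load_fixture`.
FIXTURES = ("table1", "table2", "table6")

_FLOAT_FMT = "%.12g"


class FormatError(ValueError):
    """Raised for malformed input files."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A features x samples numeric matrix with a scale tag.

    ``scale`` is ``"counts"`` (non-negative raw counts) or
    ``"log_normalized"`` (log2 of size-factor-normalised counts).
    """

    values: pd.DataFrame
    scale: str = "counts"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate feature id {dup!r}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        if self.scale == "counts" and (self.values.to_numpy() < 0).any():
            raise ValueError("counts-scale matrix contains negative values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_features(self, features: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(features)], scale=self.scale)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(samples)], scale=self.scale)


@dataclass
class ConditionMap:
    """Mapping of sample id to condition label (e.g. control / linseed / safflower)."""

    mapping: dict[str, str]

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.mapping.values():
            seen.setdefault(c, None)
        return list(seen)

    def samples_in(self, condition: str) -> list[str]:
        return [s for s, c in self.mapping.items() if c == condition]

    def validate_against(self, expr: ExpressionMatrix) -> None:
        missing = [s for s in expr.sample_ids if s not in self.mapping]
        if missing:
            raise ValueError(f"samples not mapped to a condition: {missing}")
        for cond in self.conditions:
            if len(self.samples_in(cond)) < 2:
                raise ValueError(f"condition {cond!r} has fewer than 2 samples")


@dataclass
class PhenotypeTable:
    """Samples x traits numeric table; NaN marks a missing measurement."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise FormatError(f"duplicate trait name {dup!r}")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")

    @property
    def trait_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class TargetPredictionTable:
    """Predicted miRNA->gene links with context++ scores and percentiles."""

    table: pd.DataFrame  # columns: mirna_id, gene_id, context_score, context_percentile

    REQUIRED = ("mirna_id", "gene_id", "context_score", "context_percentile")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise FormatError(f"target table missing column {col!r}")
        pairs = self.table[["mirna_id", "gene_id"]]
        if pairs.duplicated().any():
            row = pairs[pairs.duplicated()].iloc[0]
            raise FormatError(
                f"duplicate target pair ({row['mirna_id']}, {row['gene_id']})"
            )
        pct = self.table["context_percentile"].to_numpy(dtype=float)
        if ((pct < 0) | (pct > 100)).any():
            raise ValueError("context_percentile outside [0, 100]")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GeneSetCollection:
    """Named gene sets: set name -> (description, ordered member list)."""

    sets: dict[str, tuple[str, list[str]]]

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} has no members")

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]

    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class PrintedFixture:
    """A packaged transcription of one of the curated reference tables."""

    name: str
    table: pd.DataFrame
    flags: list[str] = field(default_factory=list)


@dataclass
class Edge:
    source: str
    target: str
    sign: int
    weight: float
    kind: str  # mirna_gene | mirna_trait | gene_trait


# ---------------------------------------------------------------------------
# delimited-file helpers
# ---------------------------------------------------------------------------


def _sniff_delimiter(first_line: str) -> str:
    # only tab and comma are supported; tab wins when both occur
    if "\t" in first_line:
        return "\t"
    if "," in first_line:
        return ","
    return "\t"


def _read_table_rows(path: str | Path) -> tuple[list[str], list[list[str]], str]:
    """Read a delimited file into (header, body rows); strict about raggedness."""
    path = Path(path)
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first:
            raise FormatError(f"{path}: empty file")
        delim = _sniff_delimiter(first)
        header = next(csv.reader([first], delimiter=delim))
        rows = list(csv.reader(fh, delimiter=delim))
    ncol = len(header)
    for i, row in enumerate(rows, start=2):
        if not row:
            continue
        if len(row) != ncol:
            raise FormatError(f"row {i}: expected {ncol - 1} values")
    return header, [r for r in rows if r], delim


def _parse_float(cell: str, where: str) -> float:
    try:
        return float(cell)
    except ValueError:
        raise FormatError(f"non-numeric value {cell!r} at {where}") from None


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_expression(path: str | Path, scale: str = "counts") -> ExpressionMatrix:
    """Read a features-in-rows expression table (first column = feature ids)."""
    header, rows, _ = _read_table_rows(path)
    sample_ids = header[1:]
    feature_ids: list[str] = []
    data: list[list[float]] = []
    for i, row in enumerate(rows, start=2):
        feature_ids.append(row[0])
        data.append(
            [_parse_float(c, f"row {i}, column {j + 2}") for j, c in enumerate(row[1:])]
        )
    df = pd.DataFrame(data, index=feature_ids, columns=sample_ids, dtype=float)
    return ExpressionMatrix(df, scale=scale)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write a tab-separated expression table at full float precision."""
    with open(path, "w", newline="") as fh:
        fh.write("feature\t" + "\t".join(expr.sample_ids) + "\n")
        for fid, row in zip(expr.feature_ids, expr.values.to_numpy()):
            fh.write(fid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """Read a samples-in-rows phenotype table; empty cells become missing (NaN)."""
    header, rows, _ = _read_table_rows(path)
    trait_names = header[1:]
    sample_ids: list[str] = []
    data: list[list[float]] = []
    for i, row in enumerate(rows, start=2):
        sample_ids.append(row[0])
        parsed = []
        for j, cell in enumerate(row[1:]):
            if cell.strip() == "":
                parsed.append(math.nan)
            else:
                parsed.append(_parse_float(cell, f"row {i}, column {j + 2}"))
        data.append(parsed)
    df = pd.DataFrame(data, index=sample_ids, columns=trait_names, dtype=float)
    return PhenotypeTable(df)


def write_phenotypes(phen: PhenotypeTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("sample\t" + "\t".join(phen.trait_names) + "\n")
        for sid, row in zip(phen.sample_ids, phen.values.to_numpy()):
            cells = ["" if math.isnan(v) else repr(float(v)) for v in row]
            fh.write(sid + "\t" + "\t".join(cells) + "\n")


def read_condition_map(path: str | Path) -> ConditionMap:
    """Read a two-column (sample, condition) table with a header row."""
    _, rows, _ = _read_table_rows(path)
    mapping: dict[str, str] = {}
    for i, row in enumerate(rows, start=2):
        sid, cond = row[0], row[1]
        if sid in mapping:
            raise FormatError(f"row {i}: duplicate sample id {sid!r}")
        mapping[sid] = cond
    return ConditionMap(mapping)


def write_condition_map(cmap: ConditionMap, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("sample\tcondition\n")
        for sid, cond in cmap.mapping.items():
            fh.write(f"{sid}\t{cond}\n")


def read_targets(path: str | Path) -> TargetPredictionTable:
    header, rows, _ = _read_table_rows(path)
    cols = {name: k for k, name in enumerate(header)}
    for req in TargetPredictionTable.REQUIRED:
        if req not in cols:
            raise FormatError(f"target table missing column {req!r}")
    records = []
    for i, row in enumerate(rows, start=2):
        records.append(
            {
                "mirna_id": row[cols["mirna_id"]],
                "gene_id": row[cols["gene_id"]],
                "context_score": _parse_float(row[cols["context_score"]], f"row {i}"),
                "context_percentile": _parse_float(
                    row[cols["context_percentile"]], f"row {i}"
                ),
            }
        )
    return TargetPredictionTable(pd.DataFrame.from_records(records))


def write_targets(targets: TargetPredictionTable, path: str | Path) -> None:
    targets.table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name, description, then members, tab-separated."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"line {i}: no members")
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"line {i}: no members")
            if name in sets:
                raise FormatError(f"line {i}: duplicate set name {name!r}")
            deduped = list(dict.fromkeys(members))
            if len(deduped) < len(members):
                logger.warning(
                    "gene set %s: %d duplicate members removed",
                    name,
                    len(members) - len(deduped),
                )
            sets[name] = (desc, deduped)
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------


def _fixture_path(name: str) -> Path:
    return Path(str(resources.files("conexnet").joinpath(f"data/fixtures/{name}.tsv")))


def _parse_bounded(value: str) -> float:
    """Parse p/FDR cells, accepting upper-bound notation like ``<0.001``."""
    value = value.strip()
    if value.startswith("<"):
        return float(value[1:])
    return float(value)


def load_fixture(name: str) -> PrintedFixture:
    """Load a packaged reference table.

    ``table1``: trait summary (33 traits, per-period mean/SE/min/max).
    ``table2``: consensus-module members with k.ME per condition (49 rows).
    ``table6``: miRNA-mRNA-trait records with correlations and FDRs (76 rows).
    """
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}")
    path = _fixture_path(name)
    df = pd.read_csv(path, sep="\t", dtype=str)
    flags: list[str] = []
    if name == "table1":
        for col in df.columns[3:]:
            df[col] = df[col].astype(float)
        bad = df[(df["control_mean"] > df["control_max"])]
        for acro in bad["acronym"]:
            # transcribed verbatim; the printed summary row is internally
            # inconsistent (mean outside the min/max range)
            flags.append(f"{acro}: mean outside [min, max] as printed")
    elif name == "table2":
        for col in df.columns[2:]:
            df[col] = df[col].astype(float)
    elif name == "table6":
        for col in ("context_percentile", "r_pair", "r_mirna_trait", "r_gene_trait"):
            df[col] = df[col].astype(float)
        for col in ("fdr_pair", "fdr_mirna_trait", "fdr_gene_trait"):
            df[col] = df[col].map(_parse_bounded)
    return PrintedFixture(name=name, table=df, flags=flags)


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------

_SIF_RELATION = {-1: "negcorr", 0: "corr", 1: "poscorr"}


def _sorted_edges(edges: Iterable[Edge]) -> list[Edge]:
    return sorted(edges, key=lambda e: (e.source, e.target))


def write_network(edges: Iterable[Edge], path: str | Path, format: str = "tsv") -> None:
    """Export an edge list for external visualisation.

    SIF rows are ``source<TAB>relation<TAB>target`` with the relation derived
    from the edge sign; GraphML carries weight/sign/kind as edge attributes.
    Rows are written in deterministic (source, target) order.
    """
    edges = _sorted_edges(edges)
    path = Path(path)
    if format == "sif":
        with open(path, "w") as fh:
            for e in edges:
                fh.write(f"{e.source}\t{_SIF_RELATION[int(np.sign(e.sign))]}\t{e.target}\n")
    elif format == "tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tsign\tweight\tkind\n")
            for e in edges:
                fh.write(f"{e.source}\t{e.target}\t{e.sign}\t{_FLOAT_FMT % e.weight}\t{e.kind}\n")
    elif format == "graphml":
        g = nx.DiGraph()
        for e in edges:
            g.add_edge(e.source, e.target, sign=int(e.sign), weight=float(e.weight), kind=e.kind)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {format!r}; expected sif, graphml or tsv")


def read_network_graphml(path: str | Path) -> list[Edge]:
    g = nx.read_graphml(path)
    edges = [
        Edge(u, v, int(d.get("sign", 0)), float(d.get("weight", 0.0)), d.get("kind", ""))
        for u, v, d in g.edges(data=True)
    ]
    return _sorted_edges(edges)
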