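"""Over-representation analysis of gene lists against user-supplied gene sets.

The test is the one-sided upper-tail hypergeometric probability (Fisher's
exact upper tail): given a universe of U genes, a query of n genes and a set
of K genes, the p-value is P(X >= k) for the observed overlap k.  BH
correction is applied across all tested sets.  The recommended universe is
the expressed-gene background the query was drawn from.
"""

from __future__ import annotations

from collections.abc import Collection

import pandas as pd
from scipy import stats

from .core_io import GeneSetCollection
from .integration import bh_adjust

RESULT_COLUMNS = [
    "set_name",
    "overlap_count",
    "query_size",
    "set_size",
    "universe_size",
    "p_hyper",
    "fdr",
    "overlap_genes",
]


def hypergeometric_p(overlap: int, query_size: int, set_size: int, universe_size: int) -> float:
    """Upper-tail hypergeometric probability P(X >= overlap)."""
    if overlap < 0 or overlap > min(query_size, set_size):
        raise ValueError("overlap must be within [0, min(query, set)]")
    if query_size > universe_size or set_size > universe_size:
        raise ValueError("query and set sizes cannot exceed the universe")
    if overlap == 0:
        return 1.0
    return float(stats.hypergeom.sf(overlap - 1, universe_size, set_size, query_size))


def enrich(
    query_genes: Collection[str],
    sets: GeneSetCollection,
    universe: Collection[str],
    report_all: bool = False,
) -> pd.DataFrame:
    """One hypergeometric test per gene set, BH-corrected, sorted by p.

    Sets are intersected with the universe before testing; sets without any
    overlap are omitted unless ``report_all`` is set.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    query = set(query_genes)
    if not query <= universe_set:
        raise ValueError("query genes must be contained in the universe")
    rows = []
    for name in sets.names():
        members = set(sets.members(name)) & universe_set
        if not members:
            continue
        overlap = sorted(query & members)
        if not overlap and not report_all:
            continue
        p = hypergeometric_p(len(overlap), len(query), len(members), len(universe_set))
        rows.append(
            {
                "set_name": name,
                "overlap_count": len(overlap),
                "query_size": len(query),
                "set_size": len(members),
                "universe_size": len(universe_set),
                "p_hyper": p,
                "overlap_genes": ",".join(overlap),
            }
        )
    df = pd.DataFrame.from_records(
        rows,
        columns=[c for c in RESULT_COLUMNS if c != "fdr"],
    )
    if df.empty:
        df["fdr"] = pd.Series(dtype=float)
        return df[RESULT_COLUMNS]
    df["fdr"] = bh_adjust(df["p_hyper"].to_numpy())
    df = df.sort_values(["p_hyper", "set_name"]).reset_index(drop=True)
    return df[RESULT_COLUMNS]
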