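"""Topology and block statistics across structure collections.

Occurrence counting is per block instance: a topology occurring twice in
one structure counts twice.  Block counts are additionally bucketed by
vertex ranges (2-6, 7-9, >= 10), the scale bands on which most RNA
substructures concentrate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import pandas as pd

from .partition import Block

__all__ = ["CensusResult", "block_census", "ComparisonResult", "inventory_comparison"]


@dataclass
class CensusResult:
    """Per-topology frequency table plus vertex-range bucket fractions."""

    table: pd.DataFrame
    bucket_fractions: Dict[str, float]
    total_blocks: int


def _bucket(n_vertices: int) -> str:
    if n_vertices <= 6:
        return "2-6"
    if n_vertices <= 9:
        return "7-9"
    return ">=10"


def block_census(results: Sequence[Sequence[Block]]) -> CensusResult:
    """Aggregate block occurrences over a collection of partitioned structures.

    ``results`` holds one block list per structure.  The table is indexed
    by topology ID with columns ``count``, ``n_vertices``,
    ``is_pseudoknot`` and ``appears_as_whole_graph`` (the topology was some
    structure's entire dual graph, i.e. that structure partitioned into a
    single block), sorted by decreasing count then ID.
    """
    counts: Dict[str, int] = {}
    n_vertices: Dict[str, int] = {}
    pk: Dict[str, bool] = {}
    whole: Dict[str, bool] = {}
    buckets = {"2-6": 0, "7-9": 0, ">=10": 0}
    total = 0
    for blocks in results:
        for b in blocks:
            tid = b.topology_id if b.topology_id is not None else str(b.n_vertices)
            counts[tid] = counts.get(tid, 0) + 1
            n_vertices[tid] = b.n_vertices
            pk[tid] = pk.get(tid, False) or b.is_pseudoknot
            whole.setdefault(tid, False)
            if len(blocks) == 1:
                whole[tid] = True
            buckets[_bucket(b.n_vertices)] += 1
            total += 1
    table = pd.DataFrame(
        {
            "count": pd.Series(counts, dtype=int),
            "n_vertices": pd.Series(n_vertices, dtype=int),
            "is_pseudoknot": pd.Series(pk, dtype=bool),
            "appears_as_whole_graph": pd.Series(whole, dtype=bool),
        }
    )
    table.index.name = "topology_id"
    # decreasing occurrence count, ties broken by ID
    table = table.sort_index().sort_values("count", ascending=False, kind="stable")
    fractions = {k: (v / total if total else 0.0) for k, v in buckets.items()}
    return CensusResult(table=table, bucket_fractions=fractions, total_blocks=total)


@dataclass
class ComparisonResult:
    """Presence/absence matrix between groups of partitioned structures."""

    matrix: pd.DataFrame      # rows: topology IDs; columns: (group, member)
    summary: pd.DataFrame     # per-topology: per-group totals, flags

    def present_in_all(self) -> List[str]:
        return self.summary.index[self.summary["present_in_all"]].tolist()

    def exclusive_to(self, group: str) -> List[str]:
        return self.summary.index[self.summary["exclusive_to"] == group].tolist()


def inventory_comparison(
    groups: Dict[str, Sequence[Sequence[Block]]]
) -> ComparisonResult:
    """Compare block inventories between labelled groups of structures.

    ``groups`` maps a label to a list of per-structure block lists (one per
    group member).  The matrix holds occurrence counts per topology and
    member; the summary adds per-group totals, a ``present_in_all`` flag
    (found in at least one member of every group) and ``exclusive_to`` (the
    single group containing the topology, else empty).
    """
    if not groups:
        raise ValueError("at least one group is required")
    cells: Dict[str, Dict[tuple, int]] = {}
    columns = []
    for label, members in groups.items():
        for k, blocks in enumerate(members):
            col = (label, k)
            columns.append(col)
            for b in blocks:
                tid = b.topology_id if b.topology_id is not None else str(b.n_vertices)
                cells.setdefault(tid, {})[col] = cells.get(tid, {}).get(col, 0) + 1
    index = sorted(cells)
    matrix = pd.DataFrame(0, index=index,
                          columns=pd.MultiIndex.from_tuples(columns,
                                                            names=["group", "member"]))
    for tid, row in cells.items():
        for col, v in row.items():
            matrix.loc[tid, col] = v
    matrix.index.name = "topology_id"

    group_totals = matrix.T.groupby(level="group").sum().T
    present = group_totals > 0
    summary = group_totals.copy()
    summary["present_in_all"] = present.all(axis=1)
    n_groups_present = present.sum(axis=1)
    summary["exclusive_to"] = [
        present.columns[present.loc[tid]].tolist()[0] if n_groups_present[tid] == 1 else ""
        for tid in summary.index
    ]
    return ComparisonResult(matrix=matrix, summary=summary)
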