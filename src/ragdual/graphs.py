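"""Dual-graph construction from RNA secondary structures.

A dual graph represents each helix (stem of at least two stacked canonical
base pairs) as a vertex and each loop strand connecting two helices as an
edge.  Uninterrupted hairpin loops become self loops; unpaired residues at
the 5'/3' termini are not represented.  Unlike tree graphs, dual graphs
admit cycles and can therefore represent pseudoknots.

Stems are found by merging maximal runs of stacked pairs across
single-residue bulges and 1x1 internal loops; helix merging (rather than
edge suppression) is what makes the RNA degree invariant hold: counting
self loops twice, every dual graph built from a linear RNA chain has degree
sequence ``(4, ..., 4, 2)`` or ``(4, ..., 4, 3, 3)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .structure import Pair, SecondaryStructure

__all__ = [
    "Stem",
    "LoopStrand",
    "DualGraph",
    "NoStemsError",
    "find_stems",
    "build_dual_graph",
    "dual_graph_from_structure",
    "degree_sequence",
    "is_valid_rna_degree_pattern",
]


class NoStemsError(ValueError):
    """Structure has no stems; it should have been filtered out upstream."""


@dataclass(frozen=True)
class Stem:
    """A merged helix: one dual-graph vertex.

    ``pairs`` is ordered outermost-first; ``five_prime_range`` and
    ``three_prime_range`` are inclusive 1-based residue ranges covering the
    stem's two strands (including any merged single-residue bulge or 1x1
    internal-loop residues lying between runs).
    """

    index: int
    pairs: Tuple[Pair, ...]
    five_prime_range: Tuple[int, int]
    three_prime_range: Tuple[int, int]


@dataclass(frozen=True)
class LoopStrand:
    """A single-stranded backbone segment between two stem-strand endpoints.

    ``residues`` is an inclusive 1-based range or ``None`` for a zero-length
    strand (two stems directly adjacent along the backbone).  ``role`` is
    ``"edge"`` (connects two helices), ``"self_loop"`` (uninterrupted
    hairpin loop) or ``"dangling_end"`` (touches the 5' or 3' terminus; not
    represented in the graph).
    """

    role: str
    u: int
    v: int
    residues: Optional[Tuple[int, int]]


@dataclass
class DualGraph:
    """A dual graph with residue-level back-maps.

    ``edge_mult`` maps unordered vertex pairs ``(u, v)`` with ``u < v`` to
    edge multiplicities; ``self_loops`` maps vertices to hairpin self-loop
    counts.  ``stems`` and ``strands`` retain the residue-level origin of
    every vertex and edge.
    """

    n_vertices: int
    edge_mult: Dict[Tuple[int, int], int] = field(default_factory=dict)
    self_loops: Dict[int, int] = field(default_factory=dict)
    stems: List[Stem] = field(default_factory=list)
    strands: List[LoopStrand] = field(default_factory=list)

    # -- basic queries -----------------------------------------------------

    def degree(self, v: int, count_self_loops: bool = True) -> int:
        d = sum(m for (a, b), m in self.edge_mult.items() if v in (a, b))
        if count_self_loops:
            d += 2 * self.self_loops.get(v, 0)
        return d

    def total_edge_multiplicity(self) -> int:
        return sum(self.edge_mult.values())

    def adjacency(self) -> np.ndarray:
        """Adjacency matrix of edge multiplicities (self loops excluded)."""
        a = np.zeros((self.n_vertices, self.n_vertices))
        for (u, v), m in self.edge_mult.items():
            a[u, v] = a[v, u] = m
        return a

    def is_connected(self) -> bool:
        if self.n_vertices <= 1:
            return True
        seen = {0}
        stack = [0]
        adj: Dict[int, set] = {v: set() for v in range(self.n_vertices)}
        for (u, v), m in self.edge_mult.items():
            if m > 0:
                adj[u].add(v)
                adj[v].add(u)
        while stack:
            u = stack.pop()
            for w in adj[u] - seen:
                seen.add(w)
                stack.append(w)
        return len(seen) == self.n_vertices

    # -- export ------------------------------------------------------------

    def to_edgelist_text(self) -> str:
        """One line per distinct edge: ``u v mult``; self loops as ``u u count``."""
        lines = [f"{u} {v} {m}" for (u, v), m in sorted(self.edge_mult.items())]
        lines += [f"{v} {v} {c}" for v, c in sorted(self.self_loops.items())]
        return "\n".join(lines) + ("\n" if lines else "")

    def to_adjacency_json(self) -> str:
        return json.dumps(
            {
                "n_vertices": self.n_vertices,
                "adjacency": self.adjacency().astype(int).tolist(),
                "self_loops": {str(v): c for v, c in sorted(self.self_loops.items())},
            },
            sort_keys=True,
        )


# ---------------------------------------------------------------------------
# stem finding

#: Residue-gap patterns (5'-strand gap, 3'-strand gap) between two stacked
#: runs that are bridged into one helix: a single-residue bulge on exactly
#: one strand, or a 1x1 internal loop.  Larger gaps never merge.
_MERGE_GAPS = {(1, 0), (0, 1), (1, 1)}


def _stacked_runs(ss: SecondaryStructure) -> List[List[Pair]]:
    """Maximal runs of consecutively stacked pairs, sorted by 5' start."""
    runs: List[List[Pair]] = []
    for i, j in ss.sorted_pairs():
        if runs and runs[-1][-1] == (i - 1, j + 1):
            runs[-1].append((i, j))
        else:
            runs.append([(i, j)])
    return runs


def find_stems(ss: SecondaryStructure) -> List[Stem]:
    """Find helices, merging runs across 1-nt bulges and 1x1 internal loops.

    Merging is transitive and requires the gap residues to be unpaired.
    Merged groups with fewer than two total pairs (isolated single pairs)
    are discarded.  Stems are indexed by 5'-to-3' order of their first pair.
    """
    runs = _stacked_runs(ss)
    paired = set()
    for i, j in ss.pairs:
        paired.add(i)
        paired.add(j)

    groups: List[List[List[Pair]]] = []
    for run in runs:
        if groups:
            prev = groups[-1][-1]
            e5, e3 = prev[-1]           # innermost pair of previous run
            s5, s3 = run[0]             # outermost pair of this run
            gap5, gap3 = s5 - e5 - 1, e3 - s3 - 1
            if (gap5, gap3) in _MERGE_GAPS:
                gap_res = list(range(e5 + 1, s5)) + list(range(s3 + 1, e3))
                if not any(r in paired for r in gap_res):
                    groups[-1].append(run)
                    continue
        groups.append([run])

    stems: List[Stem] = []
    for group in groups:
        pairs = [p for run in group for p in run]
        if len(pairs) < 2:
            continue
        fives = [i for i, _ in pairs]
        threes = [j for _, j in pairs]
        stems.append(
            Stem(
                index=len(stems),
                pairs=tuple(pairs),
                five_prime_range=(min(fives), max(fives)),
                three_prime_range=(min(threes), max(threes)),
            )
        )
    return stems


# ---------------------------------------------------------------------------
# graph construction

def build_dual_graph(stems: Sequence[Stem], ss: SecondaryStructure) -> DualGraph:
    """Build the dual graph of ``ss`` from its stems.

    The backbone is walked 5' to 3' over the stem-strand intervals; each
    maximal segment between two consecutive intervals (length >= 0) becomes
    nothing if it touches a terminus (dangling end), a self loop if it
    closes a hairpin, else one edge between the owning stems.  Zero-length
    segments still produce edges and self loops.
    """
    if not stems:
        raise NoStemsError("no_stems")

    intervals: List[Tuple[int, int, int, str]] = []  # (start, end, stem, side)
    for s in stems:
        intervals.append((*s.five_prime_range, s.index, "five"))
        intervals.append((*s.three_prime_range, s.index, "three"))
    intervals.sort()

    g = DualGraph(n_vertices=len(stems), stems=list(stems))

    def add_edge(u: int, v: int) -> None:
        key = (min(u, v), max(u, v))
        g.edge_mult[key] = g.edge_mult.get(key, 0) + 1

    first_start = intervals[0][0]
    if first_start > 1:
        g.strands.append(
            LoopStrand("dangling_end", intervals[0][2], intervals[0][2],
                       (1, first_start - 1))
        )
    last_end = intervals[-1][1]
    if last_end < ss.length:
        g.strands.append(
            LoopStrand("dangling_end", intervals[-1][2], intervals[-1][2],
                       (last_end + 1, ss.length))
        )

    for (s1, e1, u, side_u), (s2, e2, v, side_v) in zip(intervals, intervals[1:]):
        residues = (e1 + 1, s2 - 1) if s2 - e1 > 1 else None
        if u == v and side_u == "five" and side_v == "three":
            g.self_loops[u] = g.self_loops.get(u, 0) + 1
            g.strands.append(LoopStrand("self_loop", u, u, residues))
        else:
            add_edge(u, v)
            g.strands.append(LoopStrand("edge", u, v, residues))
    return g


def dual_graph_from_structure(ss: SecondaryStructure) -> DualGraph:
    """Convenience: :func:`find_stems` then :func:`build_dual_graph`."""
    return build_dual_graph(find_stems(ss), ss)


# ---------------------------------------------------------------------------
# degree checks

def degree_sequence(g: DualGraph, count_self_loops: bool = True) -> List[int]:
    """Ascending per-vertex degrees (self loops add 2 when counted)."""
    return sorted(g.degree(v, count_self_loops) for v in range(g.n_vertices))


def is_valid_rna_degree_pattern(g: DualGraph) -> bool:
    """Check whether a graph can represent a linear RNA chain.

    Every helix is attached to four loop strands (self loops counted twice)
    except the end helix (two strands) or the two end helices (three each),
    so the full degree sequence is ``(4, ..., 4, 2)`` or ``(4, ..., 4, 3, 3)``.

    For a graph carrying explicit self loops the sequence is checked
    literally (self loops counted twice).  For a topology-level graph
    without self loops the check is achievability: self loops can raise any
    even degree to 4 and any odd degree to 3, so the pattern is reachable
    iff all degrees are <= 4 and either exactly two vertices have odd
    degree, or none do and at least one vertex has degree <= 2.
    """
    if any(c > 0 for c in g.self_loops.values()):
        degs = degree_sequence(g, count_self_loops=True)
        if any(d > 4 for d in degs):
            return False
        non4 = [d for d in degs if d != 4]
        return non4 == [2] or non4 == [3, 3]
    degs = degree_sequence(g, count_self_loops=False)
    if not degs or max(degs) > 4:
        return False
    odd = sum(1 for d in degs if d % 2)
    return odd == 2 or (odd == 0 and min(degs) <= 2)
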