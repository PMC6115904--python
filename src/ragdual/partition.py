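"""Partition dual graphs into non-separable blocks.

A vertex is an articulation point if its removal disconnects the graph; a
subgraph with no articulation point that cannot be divided further is a
*block* (a biconnected component).  Partitioning a dual graph into blocks
keeps junctions and pseudoknots intact by construction: every cycle —
including the multi-edge cycles created by crossing base pairs — lies
wholly inside one block.  Bridges become 2-vertex single-edge blocks, and
two blocks share at most one vertex (an articulation point of the parent).

Articulation points and blocks are computed with the Hopcroft-Tarjan
depth-first low-link method adapted to multigraphs: every edge instance
carries its own identity, so a double or triple edge is never a bridge and
a parallel edge to the DFS parent acts as a back edge.  Self loops are
metadata carried with their vertex; they never affect block boundaries and
are excluded from the pseudoknot degree count.

A block corresponds to a pseudoknot iff some vertex has three or more
incident edges within the block, self loops not counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .graphs import DualGraph
from .spectral import TopologyCatalog, assign_topology_id
from .structure import SecondaryStructure

logger = logging.getLogger(__name__)

__all__ = [
    "Block",
    "find_articulation_points",
    "partition_blocks",
    "classify_pseudoknot",
    "partition_structure",
]


@dataclass
class Block:
    """A non-separable subgraph of a parent dual graph.

    ``vertices`` keeps the parent's vertex ids (sorted); ``edge_mult`` the
    induced multiplicities on those ids; ``carried_self_loops`` the
    parent's hairpin self loops at member vertices (metadata only).
    """

    vertices: Tuple[int, ...]
    edge_mult: Dict[Tuple[int, int], int]
    carried_self_loops: Dict[int, int] = field(default_factory=dict)
    is_pseudoknot: bool = False
    topology_id: Optional[str] = None

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def local_index(self) -> Dict[int, int]:
        """Parent vertex id -> 0-based index within the block."""
        return {v: k for k, v in enumerate(self.vertices)}

    def degree_within(self, v: int) -> int:
        """Summed incident edge multiplicity of ``v`` inside the block
        (self loops excluded)."""
        return sum(m for (a, b), m in self.edge_mult.items() if v in (a, b))

    def as_dual_graph(self) -> DualGraph:
        """Re-indexed standalone graph (self loops carried over) for
        spectral work or re-partitioning."""
        idx = self.local_index()
        return DualGraph(
            n_vertices=self.n_vertices,
            edge_mult={
                (min(idx[a], idx[b]), max(idx[a], idx[b])): m
                for (a, b), m in self.edge_mult.items()
            },
            self_loops={idx[v]: c for v, c in self.carried_self_loops.items() if c},
        )


# ---------------------------------------------------------------------------
# Hopcroft-Tarjan on multigraphs

def _edge_instances(g: DualGraph) -> List[Tuple[int, int]]:
    edges = []
    for (u, v), m in sorted(g.edge_mult.items()):
        edges.extend([(u, v)] * m)
    return edges


def _require_connected(g: DualGraph) -> None:
    if not g.is_connected():
        raise ValueError("graph must be connected")


def _dfs_biconnected(
    g: DualGraph,
) -> Tuple[Set[int], List[List[int]]]:
    """Iterative DFS returning (articulation points, blocks as edge-id lists).

    Each parallel edge instance has a distinct id, so multi-edges form
    2-vertex blocks rather than bridges, and self loops are ignored
    entirely.
    """
    edges = _edge_instances(g)
    adj: List[List[Tuple[int, int]]] = [[] for _ in range(g.n_vertices)]
    for eid, (u, v) in enumerate(edges):
        adj[u].append((v, eid))
        adj[v].append((u, eid))

    disc = [-1] * g.n_vertices
    low = [0] * g.n_vertices
    articulation: Set[int] = set()
    components: List[List[int]] = []
    edge_stack: List[int] = []
    counter = 0

    for root in range(g.n_vertices):
        if disc[root] != -1:
            continue
        root_children = 0
        # frames: (vertex, incoming edge id, iterator index into adj)
        stack: List[List[int]] = [[root, -1, 0]]
        disc[root] = low[root] = counter
        counter += 1
        while stack:
            frame = stack[-1]
            u, in_edge, ptr = frame
            if ptr < len(adj[u]):
                frame[2] += 1
                w, eid = adj[u][ptr]
                if eid == in_edge:
                    continue
                if disc[w] == -1:
                    edge_stack.append(eid)
                    disc[w] = low[w] = counter
                    counter += 1
                    if u == root:
                        root_children += 1
                    stack.append([w, eid, 0])
                elif disc[w] < disc[u]:
                    edge_stack.append(eid)
                    low[u] = min(low[u], disc[w])
            else:
                stack.pop()
                if not stack:
                    break
                parent = stack[-1][0]
                low[parent] = min(low[parent], low[u])
                if low[u] >= disc[parent]:
                    # pop one biconnected component, ending at the tree
                    # edge parent -> u
                    comp: List[int] = []
                    while edge_stack:
                        eid = edge_stack.pop()
                        comp.append(eid)
                        if eid == in_edge:
                            break
                    components.append(comp)
                    if parent != root or root_children > 1:
                        articulation.add(parent)
        # a root with >= 2 tree children is an articulation point
        if root_children > 1:
            articulation.add(root)
    return articulation, components


def find_articulation_points(g: DualGraph) -> Set[int]:
    """Vertices whose removal disconnects the (connected) graph."""
    _require_connected(g)
    articulation, _ = _dfs_biconnected(g)
    return articulation


def classify_pseudoknot(b: Block) -> bool:
    """True iff some vertex has degree >= 3 within the block, self loops
    not counted — the dual-graph signature of crossing base pairs."""
    return any(b.degree_within(v) >= 3 for v in b.vertices)


def partition_blocks(g: DualGraph) -> List[Block]:
    """Biconnected components of a connected dual graph, as blocks.

    Bridges become 2-vertex single-edge blocks.  Every non-self-loop edge
    instance of the parent lands in exactly one block; self loops travel
    with their vertex into every block containing it.  Blocks are sorted by
    their smallest vertex id.  A single-vertex graph has nothing to
    partition and returns an empty list with a warning.
    """
    _require_connected(g)
    if g.n_vertices < 2:
        logger.warning("single-vertex graph: nothing to partition")
        return []
    edges = _edge_instances(g)
    _, components = _dfs_biconnected(g)
    blocks = []
    for comp in components:
        mult: Dict[Tuple[int, int], int] = {}
        vs: Set[int] = set()
        for eid in comp:
            u, v = edges[eid]
            key = (min(u, v), max(u, v))
            mult[key] = mult.get(key, 0) + 1
            vs.update(key)
        b = Block(
            vertices=tuple(sorted(vs)),
            edge_mult=mult,
            carried_self_loops={
                v: g.self_loops[v] for v in sorted(vs) if g.self_loops.get(v)
            },
        )
        b.is_pseudoknot = classify_pseudoknot(b)
        blocks.append(b)
    blocks.sort(key=lambda b: b.vertices)
    return blocks


def partition_structure(
    ss: SecondaryStructure,
    cat: TopologyCatalog,
    graph: Optional[DualGraph] = None,
) -> List[Block]:
    """Full pipeline: build the dual graph, partition it, and assign each
    block a topology ID from the catalog via its Laplacian spectrum.

    ``ss`` must already have passed canonical filtering and the dataset
    filter (at least two stems).  Blocks of the same topology but different
    self-loop counts share an ID, since self loops are invisible to the
    spectrum.  Pass ``graph`` to reuse an already-built dual graph.
    """
    from .graphs import dual_graph_from_structure

    g = graph if graph is not None else dual_graph_from_structure(ss)
    if g.n_vertices < 2:
        raise ValueError(
            "structure yields a dual graph with < 2 vertices; "
            "apply the dataset filter upstream"
        )
    blocks = partition_blocks(g)
    for b in blocks:
        b.topology_id = assign_topology_id(b.as_dual_graph(), cat)
    return blocks
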