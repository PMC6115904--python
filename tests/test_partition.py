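"""Articulation points, blocks and pseudoknot classification."""

import itertools

import networkx as nx
import pytest

from ragdual import (
    Block,
    DualGraph,
    classify_pseudoknot,
    dual_graph_from_structure,
    find_articulation_points,
    parse_dotbracket,
    partition_blocks,
    partition_structure,
)

from conftest import make_nested, make_pseudoknotted, random_multigraph


# ---------------------------------------------------------------------------
# independent oracles

def brute_force_articulation(g: DualGraph):
    """v is an articulation point iff deleting v disconnects the rest."""
    if g.n_vertices <= 2:
        return set()
    out = set()
    for v in range(g.n_vertices):
        rest = [u for u in range(g.n_vertices) if u != v]
        adj = {u: set() for u in rest}
        for (a, b), m in g.edge_mult.items():
            if m and v not in (a, b):
                adj[a].add(b)
                adj[b].add(a)
        seen, stack = {rest[0]}, [rest[0]]
        while stack:
            u = stack.pop()
            for w in adj[u] - seen:
                seen.add(w)
                stack.append(w)
        if len(seen) != len(rest):
            out.add(v)
    return out


def brute_force_blocks(g: DualGraph):
    """Maximal vertex subsets inducing a connected, articulation-free
    sub-multigraph with at least one edge."""
    candidates = []
    for r in range(2, g.n_vertices + 1):
        for subset in itertools.combinations(range(g.n_vertices), r):
            sub = {
                (a, b): m for (a, b), m in g.edge_mult.items()
                if a in subset and b in subset
            }
            if not sub:
                continue
            h = DualGraph(n_vertices=len(subset),
                          edge_mult={
                              (subset.index(a), subset.index(b)): m
                              for (a, b), m in sub.items()
                          })
            if h.is_connected() and not brute_force_articulation(h):
                candidates.append(frozenset(subset))
    return {c for c in candidates if not any(c < d for d in candidates)}


def networkx_blocks(g: DualGraph):
    """Biconnected components via networkx on a simple expansion: every
    parallel edge instance beyond the first is subdivided by a dummy node."""
    h = nx.Graph()
    h.add_nodes_from(range(g.n_vertices))
    dummy = g.n_vertices
    for (u, v), m in g.edge_mult.items():
        h.add_edge(u, v)
        for _ in range(m - 1):
            h.add_edge(u, dummy)
            h.add_edge(dummy, v)
            dummy += 1
    return {
        frozenset(x for x in comp if x < g.n_vertices)
        for comp in nx.biconnected_components(h)
        if len(frozenset(x for x in comp if x < g.n_vertices)) >= 2
    }


class TestArticulationPoints:
    def test_path_center_is_articulation(self):
        g = DualGraph(n_vertices=3, edge_mult={(0, 1): 1, (1, 2): 1})
        assert find_articulation_points(g) == {1}

    def test_triple_edge_has_none(self):
        g = DualGraph(n_vertices=2, edge_mult={(0, 1): 3})
        assert find_articulation_points(g) == set()

    def test_disconnected_rejected(self):
        g = DualGraph(n_vertices=4, edge_mult={(0, 1): 1, (2, 3): 1})
        with pytest.raises(ValueError, match="connected"):
            find_articulation_points(g)

    @pytest.mark.parametrize("seed", range(150))
    def test_matches_brute_force_deletion(self, seed):
        g = random_multigraph(seed)
        assert find_articulation_points(g) == brute_force_articulation(g)


class TestBlocks:
    def test_bridge_and_internal_loop_split(self):
        g = DualGraph(n_vertices=3, edge_mult={(0, 1): 2, (1, 2): 1})
        blocks = partition_blocks(g)
        assert [(b.vertices, b.edge_mult) for b in blocks] == [
            ((0, 1), {(0, 1): 2}),
            ((1, 2), {(1, 2): 1}),
        ]

    def test_biconnected_graph_is_one_block(self):
        cyc = DualGraph(n_vertices=4,
                        edge_mult={(0, 1): 1, (1, 2): 1, (2, 3): 1, (0, 3): 1})
        (b,) = partition_blocks(cyc)
        assert b.vertices == (0, 1, 2, 3)

    def test_single_vertex_graph_yields_nothing(self, caplog):
        g = DualGraph(n_vertices=1, self_loops={0: 1})
        assert partition_blocks(g) == []

    def test_self_loops_carried_not_partitioned(self):
        g = DualGraph(n_vertices=3, edge_mult={(0, 1): 2, (1, 2): 1},
                      self_loops={0: 1, 2: 1})
        blocks = partition_blocks(g)
        assert blocks[0].carried_self_loops == {0: 1}
        assert blocks[1].carried_self_loops == {2: 1}

    @pytest.mark.parametrize("seed", range(150))
    def test_matches_brute_force_and_networkx(self, seed):
        g = random_multigraph(seed)
        ours = {frozenset(b.vertices) for b in partition_blocks(g)}
        assert ours == brute_force_blocks(g)
        assert ours == networkx_blocks(g)

    @pytest.mark.parametrize("seed", range(60))
    def test_edge_conservation_and_idempotence(self, seed):
        g = random_multigraph(seed)
        blocks = partition_blocks(g)
        merged = {}
        for b in blocks:
            for e, m in b.edge_mult.items():
                merged[e] = merged.get(e, 0) + m
        assert merged == {e: m for e, m in g.edge_mult.items() if m}
        for b in blocks:
            rb = partition_blocks(b.as_dual_graph())
            assert len(rb) == 1
            assert rb[0].edge_mult == b.as_dual_graph().edge_mult

    def test_shared_vertices_are_articulation_points(self):
        g = random_multigraph(7)
        blocks = partition_blocks(g)
        arts = find_articulation_points(g)
        for b1, b2 in itertools.combinations(blocks, 2):
            shared = set(b1.vertices) & set(b2.vertices)
            assert len(shared) <= 1
            assert shared <= arts


class TestPseudoknotClassification:
    @pytest.mark.parametrize(
        "edge_mult, n, expected",
        [
            ({(0, 1): 3}, 2, True),                       # two-helix pseudoknot
            ({(0, 1): 1, (0, 2): 1, (1, 2): 1}, 3, False),  # 3-way junction
            ({(0, 1): 1}, 2, False),
        ],
    )
    def test_degree_three_rule(self, edge_mult, n, expected):
        b = Block(vertices=tuple(range(n)), edge_mult=edge_mult)
        assert classify_pseudoknot(b) is expected

    def test_self_loops_not_counted(self):
        b = Block(vertices=(0, 1), edge_mult={(0, 1): 2},
                  carried_self_loops={0: 1})
        assert classify_pseudoknot(b) is False


class TestPartitionStructure:
    def test_h_type_pseudoknot_single_block(self, catalog):
        blocks = partition_structure(
            parse_dotbracket("((((..[[[[...))))..]]]]"), catalog)
        assert [(b.topology_id, b.is_pseudoknot) for b in blocks] == [("2_3", True)]

    def test_internal_loop_block(self, catalog):
        blocks = partition_structure(parse_dotbracket("((..((...))..))"), catalog)
        assert [(b.topology_id, b.is_pseudoknot) for b in blocks] == [("2_2", False)]

    def test_three_way_junction_block(self, catalog):
        blocks = partition_structure(
            parse_dotbracket("((..((...))((...))..))"), catalog)
        assert [(b.topology_id, b.is_pseudoknot) for b in blocks] == [("3_5", False)]

    def test_junction_never_split(self, catalog):
        # hairpin arm bridged to a 4-way junction: the 4-cycle stays whole
        text = "((...))((..((...))((...))((...))..))"
        blocks = partition_structure(parse_dotbracket(text), catalog)
        ids = sorted(b.topology_id for b in blocks)
        assert ids == ["2_1", "4_19"]
        four_way = [b for b in blocks if b.topology_id == "4_19"]
        assert len(four_way[0].vertices) == 4

    def test_same_topology_despite_extra_hairpins(self, catalog):
        plain = partition_structure(parse_dotbracket("((..((...))..))"), catalog)
        # same two-stem internal loop, but embedded so both stems carry loops
        other = partition_structure(
            parse_dotbracket("((..((...))..))((...))"), catalog)
        assert plain[0].topology_id == "2_2"
        assert "2_2" in [b.topology_id for b in other]

    @pytest.mark.parametrize("seed", range(40))
    def test_pseudoknot_flags_match_crossing_oracle(self, catalog, seed):
        nested = make_nested(seed)
        assert not nested.has_crossing()
        assert not any(
            b.is_pseudoknot for b in partition_structure(nested, catalog)
        )
        pk = make_pseudoknotted(seed)
        assert pk.has_crossing()
        assert any(b.is_pseudoknot for b in partition_structure(pk, catalog))
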