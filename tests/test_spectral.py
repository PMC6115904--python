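"""Laplacians, spectra, topology IDs and catalog persistence."""

import numpy as np
import pytest

from ragdual import (
    CatalogIntegrityError,
    DualGraph,
    assign_topology_id,
    build_catalog,
    dual_graph_from_structure,
    laplacian,
    load_catalog,
    parse_dotbracket,
    save_catalog,
    spectrum,
)
from ragdual.spectral import CatalogEntry, TopologyCatalog, graph_spectrum_key

from conftest import make_nested, relabel


class TestLaplacian:
    @pytest.mark.parametrize(
        "edge_mult, self_loops, expected",
        [
            ({(0, 1): 1}, {}, [[1, -1], [-1, 1]]),
            ({(0, 1): 2}, {}, [[2, -2], [-2, 2]]),
            ({(0, 1): 2}, {1: 1}, [[2, -2], [-2, 2]]),  # self loops ignored
        ],
    )
    def test_definition(self, edge_mult, self_loops, expected):
        g = DualGraph(n_vertices=2, edge_mult=edge_mult, self_loops=self_loops)
        assert np.array_equal(laplacian(g), np.array(expected, dtype=float))

    def test_rows_sum_to_zero_and_trace_counts_strands(self):
        g = dual_graph_from_structure(parse_dotbracket("((..((...))..))"))
        l_matrix = laplacian(g)
        assert np.allclose(l_matrix.sum(axis=1), 0)
        assert l_matrix.trace() == 2 * g.total_edge_multiplicity()


class TestSpectrum:
    @pytest.mark.parametrize(
        "mult, expected",
        [(1, (0.0, 2.0)), (2, (0.0, 4.0)), (3, (0.0, 6.0))],
    )
    def test_two_vertex_closed_form(self, mult, expected):
        g = DualGraph(n_vertices=2, edge_mult={(0, 1): mult})
        assert spectrum(laplacian(g)) == pytest.approx(expected)

    def test_nonsymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            spectrum(np.array([[1.0, -1.0], [0.0, 1.0]]))

    @pytest.mark.parametrize("seed", range(15))
    def test_connected_graph_spectral_sanity(self, seed):
        """First eigenvalue exactly 0, Fiedler eigenvalue positive."""
        g = dual_graph_from_structure(make_nested(seed))
        ev = spectrum(laplacian(g))
        assert ev[0] == 0.0
        assert np.all(ev >= 0)
        if g.n_vertices > 1:
            assert ev[1] > 1e-9


class TestTopologyIds:
    def test_two_vertex_ids(self, catalog):
        for mult, expected in [(1, "2_1"), (2, "2_2"), (3, "2_3")]:
            g = DualGraph(n_vertices=2, edge_mult={(0, 1): mult})
            assert assign_topology_id(g, catalog) == expected

    def test_junction_cycles_get_published_ids(self, catalog):
        for n, expected in [(3, "3_5"), (4, "4_19"), (5, "5_2")]:
            cyc = {(i, (i + 1) % n): 1 for i in range(n)}
            cyc = {(min(u, v), max(u, v)): 1 for (u, v) in cyc}
            g = DualGraph(n_vertices=n, edge_mult=cyc)
            assert assign_topology_id(g, catalog) == expected

    def test_out_of_range_reports_vertex_count_only(self, catalog):
        n = 12
        g = DualGraph(n_vertices=n,
                      edge_mult={(i, i + 1): 1 for i in range(n - 1)})
        assert assign_topology_id(g, catalog) == "12"
        g1 = DualGraph(n_vertices=1, self_loops={0: 1})
        assert assign_topology_id(g1, catalog) == "1"

    def test_unmatched_in_range_returns_new_sentinel(self, catalog):
        # all-degree-4 triangle: valid multigraph, not an RNA topology
        g = DualGraph(n_vertices=3, edge_mult={(0, 1): 2, (0, 2): 2, (1, 2): 2})
        assert assign_topology_id(g, catalog) == "3_new"

    def test_disconnected_graph_rejected(self, catalog):
        g = DualGraph(n_vertices=4, edge_mult={(0, 1): 1, (2, 3): 1})
        with pytest.raises(ValueError, match="connected"):
            assign_topology_id(g, catalog)

    @pytest.mark.parametrize("seed", range(10))
    def test_isomorphic_relabelings_share_id(self, catalog, seed):
        ss = make_nested(seed, n_stems=4)
        g = dual_graph_from_structure(ss)
        rng = np.random.default_rng(seed)
        ref = assign_topology_id(g, catalog)
        for _ in range(3):
            perm = rng.permutation(g.n_vertices).tolist()
            h = relabel(g, perm)
            assert graph_spectrum_key(h) == graph_spectrum_key(g)
            assert assign_topology_id(h, catalog) == ref

    def test_self_loops_do_not_change_id(self, catalog):
        bare = DualGraph(n_vertices=2, edge_mult={(0, 1): 2})
        looped = DualGraph(n_vertices=2, edge_mult={(0, 1): 2},
                           self_loops={0: 1, 1: 1})
        assert assign_topology_id(bare, catalog) \
            == assign_topology_id(looped, catalog) == "2_2"


class TestCatalogPersistence:
    def test_roundtrip(self, catalog, tmp_path):
        path = str(tmp_path / "cat.json")
        save_catalog(catalog, path)
        loaded = load_catalog(path)
        assert loaded.max_vertices == catalog.max_vertices
        assert loaded.entries == catalog.entries
        assert loaded.aliases == catalog.aliases
        # deterministic bytes
        path2 = str(tmp_path / "cat2.json")
        save_catalog(loaded, path2)
        assert open(path).read() == open(path2).read()

    def test_catalog_v2_has_three_entries(self, catalog):
        assert sum(1 for e in catalog.entries if e.n_vertices == 2) == 3

    def test_corrupted_file_is_integrity_error(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(CatalogIntegrityError):
            load_catalog(str(path))

    def test_duplicate_spectrum_rejected(self):
        e = CatalogEntry(id="2_1", n_vertices=2, spectrum=(0.0, 2.0),
                         adjacency_upper_triangle=(1,))
        dup = CatalogEntry(id="2_9", n_vertices=2, spectrum=(0.0, 2.0),
                           adjacency_upper_triangle=(1,))
        with pytest.raises(CatalogIntegrityError, match="duplicate spectrum"):
            TopologyCatalog(max_vertices=2, entries=[e, dup])

    def test_ids_unique_per_catalog(self, catalog):
        ids = [e.id for e in catalog.entries]
        assert len(ids) == len(set(ids))
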