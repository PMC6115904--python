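"""Residue ranges, 3D fragment extraction and the fragment catalog."""

import pytest

from ragdual import (
    FragmentRecord,
    block_residues,
    catalog_fragments,
    dual_graph_from_structure,
    extract_fragment,
    parse_dotbracket,
    partition_blocks,
    partition_structure,
)
from ragdual.fragments import fragment_group
from ragdual.spectral import graph_spectrum_key
from ragdual.synthetic import synthetic_coordinates

from conftest import make_nested


def n_residues_in(structure):
    return sum(len(ch) for ch in structure[0])


class TestBlockResidues:
    def test_h_type_pseudoknot_covers_whole_chain(self):
        ss = parse_dotbracket("((((..[[[[...))))..]]]]")
        g = dual_graph_from_structure(ss)
        (b,) = partition_blocks(g)
        assert block_residues(b, g) == [(1, 23)]

    def test_bridge_block_excludes_other_arm(self):
        # hairpin S0 bridged to internal loop S1-S2
        ss = parse_dotbracket("((...))..((..((...))..))")
        g = dual_graph_from_structure(ss)
        bridge, internal = partition_blocks(g)
        assert bridge.vertices == (0, 1)
        # S0 (1-7 incl. hairpin loop), connecting strand 8-9, S1 strands
        assert block_residues(bridge, g) == [(1, 11), (23, 24)]
        assert block_residues(internal, g) == [(10, 24)]

    def test_zero_length_strand_adds_no_residues(self):
        ss = parse_dotbracket("((((...))))((((...))))")
        g = dual_graph_from_structure(ss)
        (b,) = partition_blocks(g)
        # everything is covered by stems and hairpins anyway
        assert block_residues(b, g) == [(1, 22)]

    def test_unknown_vertex_rejected(self):
        ss = parse_dotbracket("((..((...))..))")
        g = dual_graph_from_structure(ss)
        (b,) = partition_blocks(g)
        bad = type(b)(vertices=(0, 5), edge_mult=b.edge_mult)
        with pytest.raises(ValueError, match="absent"):
            block_residues(bad, g)


class TestExtractFragment:
    @pytest.fixture()
    def coords(self):
        ss = parse_dotbracket("((((..[[[[...))))..]]]]")
        return synthetic_coordinates(ss, seed=1)

    def test_full_range_keeps_all_atoms(self, coords):
        frag, gaps = extract_fragment(coords, [(1, 23)])
        assert gaps == []
        assert n_residues_in(frag) == 23

    def test_subranges_count_residues(self, coords):
        frag, gaps = extract_fragment(coords, [(1, 4), (14, 17)])
        assert gaps == []
        assert n_residues_in(frag) == 8
        nums = [r.seqid.num for r in frag[0][0]]
        assert nums == [1, 2, 3, 4, 14, 15, 16, 17]

    def test_empty_ranges_warn_and_yield_empty(self, coords, caplog):
        frag, gaps = extract_fragment(coords, [])
        assert n_residues_in(frag) == 0
        assert "empty" in caplog.text.lower()

    def test_missing_residue_reported_as_gap(self, coords):
        del coords[0][0][4]  # drop residue 5
        frag, gaps = extract_fragment(coords, [(1, 6)])
        assert gaps == [5]
        assert n_residues_in(frag) == 5

    def test_unknown_chain_rejected(self, coords):
        with pytest.raises(ValueError, match="chain"):
            extract_fragment(coords, [(1, 4)], chain="Z")


class TestCatalogFragments:
    def make_record(self, i, topology_id, **kw):
        defaults = dict(
            source_id=f"synth{i}", chain="A", topology_id=topology_id,
            block_index=0, residue_ranges=((1, 10),), n_vertices=2,
            is_pseudoknot=False,
        )
        defaults.update(kw)
        return FragmentRecord(**defaults)

    def test_grouping_by_topology(self, tmp_path):
        records = [
            self.make_record(0, "2_2"),
            self.make_record(1, "2_2"),
            self.make_record(2, "12", n_vertices=12),
        ]
        manifest = catalog_fragments(records, str(tmp_path))
        assert manifest["group"].tolist() == ["2_2", "2_2", "V>=10"]
        assert (tmp_path / "manifest.tsv").exists()
        assert (tmp_path / "2_2").is_dir()
        assert (tmp_path / "Vge10").is_dir()

    def test_vertex_count_labels(self):
        assert fragment_group("2_3") == "2_3"
        assert fragment_group("15") == "V>=10"

    def test_empty_input_empty_manifest(self, tmp_path):
        manifest = catalog_fragments([], str(tmp_path))
        assert len(manifest) == 0
        assert (tmp_path / "manifest.tsv").exists()

    def test_pdb_files_written_per_group(self, tmp_path):
        ss = parse_dotbracket("((..((...))..))")
        coords = {"synth0": synthetic_coordinates(ss, seed=3)}
        records = [self.make_record(0, "2_2", residue_ranges=((1, 15),))]
        catalog_fragments(records, str(tmp_path), coordinates=coords)
        pdbs = list((tmp_path / "2_2").glob("*.pdb"))
        assert len(pdbs) == 1
        assert "ATOM" in pdbs[0].read_text()


class TestReannotation:
    @pytest.mark.parametrize("seed", range(10))
    def test_single_block_fragment_reproduces_topology(self, catalog, seed):
        """Restricting pairs to a block's residue ranges and rebuilding the
        graph reproduces the block topology for single-block structures."""
        ss = make_nested(seed, n_stems=2)  # two stems: always a single block
        blocks = partition_structure(ss, catalog)
        assert len(blocks) == 1
        g = dual_graph_from_structure(ss)
        ranges = block_residues(blocks[0], g)
        kept = {
            (i, j) for (i, j) in ss.pairs
            if any(s <= i <= e for s, e in ranges)
            and any(s <= j <= e for s, e in ranges)
        }
        sub = ss.with_pairs(kept)
        g2 = dual_graph_from_structure(sub)
        assert graph_spectrum_key(g2) \
            == graph_spectrum_key(blocks[0].as_dual_graph())
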