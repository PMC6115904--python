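"""Residue-level substructure fragments for dual-graph blocks.

Each block maps back to the residues of its member stems plus the loop
strands realizing its edges and the hairpin loops of its member vertices.
Given 3D coordinates (PDB or mmCIF, read with gemmi) the corresponding
atomic fragments can be cut out and cataloged by topology ID, building a
library of RNA substructures indexed by their dual-graph block topology
(the RAG-3Dual organisation).

Residues of a stem shared between two blocks (an articulation vertex) are
duplicated into both fragments, so every fragment is a self-contained
substructure.  Dangling 5'/3' residues are never included: they are not
part of the graph.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import gemmi
import pandas as pd

from .graphs import DualGraph
from .partition import Block

logger = logging.getLogger(__name__)

__all__ = [
    "FragmentRecord",
    "block_residues",
    "extract_fragment",
    "catalog_fragments",
    "fragment_group",
]

Range = Tuple[int, int]


@dataclass(frozen=True)
class FragmentRecord:
    """One cataloged substructure: provenance plus block metadata."""

    source_id: str
    chain: str
    topology_id: str
    block_index: int
    residue_ranges: Tuple[Range, ...]
    n_vertices: int
    is_pseudoknot: bool


def _merge_ranges(ranges: List[Range]) -> List[Range]:
    """Merge overlapping and backbone-adjacent ranges into maximal disjoint ones."""
    out: List[Range] = []
    for s, e in sorted(ranges):
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def block_residues(b: Block, g: DualGraph) -> List[Range]:
    """Inclusive residue ranges covered by a block.

    Union of the member stems' strand ranges, the residues of loop strands
    realizing the block's edges (an edge between two block members always
    belongs to this block: two blocks never share two vertices), and the
    hairpin self-loop residues of member vertices; merged into maximal
    disjoint ranges.  Zero-length strands contribute nothing.
    """
    members = set(b.vertices)
    for v in members:
        if v >= g.n_vertices:
            raise ValueError(f"block vertex {v} absent from parent graph")
    ranges: List[Range] = []
    for v in members:
        stem = g.stems[v]
        ranges.append(stem.five_prime_range)
        ranges.append(stem.three_prime_range)
    for strand in g.strands:
        if strand.residues is None:
            continue
        if strand.role == "edge" and strand.u in members and strand.v in members:
            ranges.append(strand.residues)
        elif strand.role == "self_loop" and strand.u in members:
            ranges.append(strand.residues)
    return _merge_ranges(ranges)


# ---------------------------------------------------------------------------
# 3D extraction

def _first_rna_chain(structure: gemmi.Structure, chain: Optional[str]) -> gemmi.Chain:
    model = structure[0]
    if chain is None:
        if len(model) == 0:
            raise ValueError("coordinate file contains no chains")
        return model[0]
    for ch in model:
        if ch.name == chain:
            return ch
    raise ValueError(f"chain {chain!r} not found in coordinate file")


def extract_fragment(
    coords: gemmi.Structure,
    ranges: Sequence[Range],
    chain: Optional[str] = None,
) -> Tuple[gemmi.Structure, List[int]]:
    """Atom records restricted to ``ranges`` on one chain.

    Residue numbering must match the 2D numbering and is preserved in the
    output.  Returns the fragment structure plus the list of residue
    numbers that fell inside a range but were missing from the coordinates
    (each is also logged as a warning).  An empty range list yields an
    empty fragment with a warning.
    """
    src_chain = _first_rna_chain(coords, chain)
    wanted = set()
    for s, e in ranges:
        wanted.update(range(s, e + 1))
    if not wanted:
        logger.warning("empty residue ranges: extracting an empty fragment")

    frag = gemmi.Structure()
    frag.name = f"{coords.name}_fragment" if coords.name else "fragment"
    model = gemmi.Model("1")
    out_chain = gemmi.Chain(src_chain.name)
    present = set()
    for res in src_chain:
        num = res.seqid.num
        if num in wanted:
            out_chain.add_residue(res.clone())
            present.add(num)
    model.add_chain(out_chain)
    frag.add_model(model)
    gaps = sorted(wanted - present)
    for num in gaps:
        logger.warning(
            "residue %d in fragment range missing from coordinates "
            "(chain %s); recorded as gap", num, src_chain.name,
        )
    frag.setup_entities()
    return frag, gaps


def fragment_group(topology_id: str) -> str:
    """Catalog group for a topology ID.

    Vertex-count-only labels (graphs outside the catalog range, >= 10
    vertices) are pooled under ``"V>=10"``; everything else groups under
    its own ID.
    """
    if re.fullmatch(r"\d+", topology_id):
        return "V>=10" if int(topology_id) >= 10 else topology_id
    return topology_id


def _safe_dirname(group: str) -> str:
    return group.replace(">=", "ge").replace("/", "_")


def catalog_fragments(
    records: Sequence[FragmentRecord],
    out_dir: str,
    coordinates: Optional[Dict[str, gemmi.Structure]] = None,
) -> pd.DataFrame:
    """Write a fragment catalog under ``out_dir`` and return its manifest.

    Fragments are grouped in per-topology directories.  When
    ``coordinates`` maps ``source_id`` to a structure, each fragment's
    atoms are written as a PDB file inside its group directory.  The
    manifest TSV (``manifest.tsv``) lists source_id, chain, topology_id,
    group, ranges and the pseudoknot flag in deterministic order.
    """
    rows = []
    for rec in sorted(
        records, key=lambda r: (fragment_group(r.topology_id), r.source_id, r.block_index)
    ):
        group = fragment_group(rec.topology_id)
        rows.append(
            {
                "source_id": rec.source_id,
                "chain": rec.chain,
                "topology_id": rec.topology_id,
                "group": group,
                "block_index": rec.block_index,
                "n_vertices": rec.n_vertices,
                "is_pseudoknot": rec.is_pseudoknot,
                "residue_ranges": ";".join(f"{s}-{e}" for s, e in rec.residue_ranges),
            }
        )
        group_dir = os.path.join(out_dir, _safe_dirname(group))
        os.makedirs(group_dir, exist_ok=True)
        if coordinates is not None and rec.source_id in coordinates:
            frag, _ = extract_fragment(
                coordinates[rec.source_id], rec.residue_ranges, rec.chain or None
            )
            path = os.path.join(
                group_dir, f"{rec.source_id}_{rec.chain}_block{rec.block_index}.pdb"
            )
            frag.write_pdb(path)
    manifest = pd.DataFrame(
        rows,
        columns=[
            "source_id", "chain", "topology_id", "group", "block_index",
            "n_vertices", "is_pseudoknot", "residue_ranges",
        ],
    )
    os.makedirs(out_dir, exist_ok=True)
    manifest.to_csv(os.path.join(out_dir, "manifest.tsv"), sep="\t", index=False)
    return manifest
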