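"""Seeded generators of synthetic secondary structures and toy coordinates.

These generators make every module testable without downloads.  Nested
structures are sampled as random ordered forests of stems realized with
helix lengths of 2-4 base pairs, hairpin loops of 3-6 nt and loop gaps
chosen so that no two distinct stems satisfy the helix-merging geometry
(single-residue bulge or 1x1 internal loop).  H-type pseudoknots are
inserted by pairing hairpin-loop residues with unpaired residues further
downstream, creating crossing pairs by construction.

Coordinates are deliberately unphysical: three atoms per residue laid on a
deterministic helical curve, sufficient for exercising fragment extraction
but carrying no thermodynamic or geometric realism.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import gemmi
import numpy as np

from .io import parse_dotbracket
from .structure import Pair, SecondaryStructure

__all__ = [
    "random_nested_structure",
    "insert_h_pseudoknot",
    "synthetic_coordinates",
    "coordinates_pdb_string",
]

_COMPLEMENT_CHOICES = [("G", "C"), ("C", "G"), ("A", "U"), ("U", "A")]


# ---------------------------------------------------------------------------
# nested structures

def _random_forest(k: int, rng: np.random.Generator) -> List[list]:
    """Random ordered forest with ``k`` nodes; each tree is (children-list)."""
    if k == 0:
        return []
    s = int(rng.integers(1, k + 1))        # size of the first tree
    first = _random_forest(s - 1, rng)     # its root takes one node
    rest = _random_forest(k - s, rng)
    return [first] + rest


def _render_forest(
    forest: List[list], rng: np.random.Generator
) -> str:
    """Dot-bracket text for a forest of stems with merge-proof gaps."""
    parts = []
    for children in forest:
        bp = int(rng.integers(2, 5))
        if children:
            inner = _render_forest(children, rng)
            g5 = int(rng.integers(0, 4))
            g3 = int(rng.integers(0, 4))
            if len(children) == 1 and g5 <= 1 and g3 <= 1:
                g5 = 2  # forbid the bulge/1x1 geometry that merges helices
            body = "." * g5 + inner + "." * g3
        else:
            body = "." * int(rng.integers(3, 7))   # hairpin loop >= 3 nt
        parts.append("(" * bp + body + ")" * bp)
        parts.append("." * int(rng.integers(0, 3)))  # gap to next sibling
    return "".join(parts[:-1]) if parts else ""


def _assign_sequence(
    length: int, pairs: frozenset, rng: np.random.Generator
) -> str:
    seq = [str(c) for c in rng.choice(list("ACGU"), size=length)]
    for i, j in sorted(pairs):
        a, b = _COMPLEMENT_CHOICES[int(rng.integers(0, 4))]
        seq[i - 1] = a
        seq[j - 1] = b
    return "".join(seq)


def random_nested_structure(
    n_residues: int, n_stems: int, seed: int
) -> SecondaryStructure:
    """A random pseudoknot-free structure with exactly ``n_stems`` helices.

    The output is reproducible per seed, contains no crossing pairs, and
    its dual graph has exactly ``n_stems`` vertices.  Residues left over
    after laying out stems and loops become 5'/3' dangling ends.  Raises
    ``ValueError`` when ``n_residues`` cannot accommodate the requested
    stems even at minimal helix and loop sizes.
    """
    if n_stems < 1:
        raise ValueError("need at least one stem")
    rng = np.random.default_rng(seed)
    for _attempt in range(8):
        forest = _random_forest(n_stems, rng)
        struct = _render_forest(forest, rng)
        if len(struct) <= n_residues:
            break
    else:
        # fall back to minimal sizes: 2 bp per stem, 3-nt hairpins, nesting
        # gaps of (2, 0); still random in shape
        forest = _random_forest(n_stems, rng)

        def minimal(forest_: List[list]) -> str:
            out = []
            for children in forest_:
                inner = minimal(children) if children else "..."
                body = ".." + inner if len(children) == 1 else inner
                out.append("((" + body + "))")
            return "".join(out)

        struct = minimal(forest)
        if len(struct) > n_residues:
            raise ValueError(
                f"{n_stems} stems do not fit in {n_residues} residues "
                f"(minimal layout needs {len(struct)})"
            )
    extra = n_residues - len(struct)
    lead = int(rng.integers(0, extra + 1))
    struct = "." * lead + struct + "." * (extra - lead)
    ss = parse_dotbracket(struct)
    sequence = _assign_sequence(n_residues, ss.pairs, rng)
    return SecondaryStructure(
        name=f"nested_s{seed}",
        length=n_residues,
        pairs=ss.pairs,
        sequence=sequence,
    )


# ---------------------------------------------------------------------------
# pseudoknot insertion

def _unpaired_runs(ss: SecondaryStructure) -> List[Tuple[int, int]]:
    pm = ss.partner_map()
    runs = []
    start = None
    for i in range(1, ss.length + 1):
        if i not in pm:
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, ss.length))
    return runs


def insert_h_pseudoknot(ss: SecondaryStructure, seed: int) -> SecondaryStructure:
    """Insert a 2-bp stem pairing hairpin-loop residues with downstream ones.

    Needs a hairpin loop of >= 4 unpaired residues with >= 4 consecutive
    unpaired residues somewhere downstream of it; raises ``ValueError``
    when no feasible site exists.  The new pairs cross the hairpin's
    closing stem, so the output always contains a pseudoknot, and a
    one-residue unpaired margin is kept on each side of the new stem so it
    neither stacks onto nor merges with existing helices.
    """
    rng = np.random.default_rng(seed)
    pm = ss.partner_map()
    runs = _unpaired_runs(ss)
    hairpins = [
        (a, b) for a, b in runs
        if b - a + 1 >= 4 and pm.get(a - 1) == b + 1
    ]
    sites = []
    for a, b in hairpins:
        for c, d in runs:
            if c > b + 1 and d - c + 1 >= 4:
                sites.append(((a, b), (c, d)))
    if not sites:
        raise ValueError("no feasible pseudoknot site")
    (a, b), (c, d) = sites[int(rng.integers(0, len(sites)))]
    p = int(rng.integers(a + 1, b - 1))      # p, p+1 inside the loop, margins kept
    q = int(rng.integers(c + 1, d - 1))      # q, q+1 downstream, margins kept
    new_pairs = {(p, q + 1), (p + 1, q)}
    seq = None
    if ss.sequence is not None:
        chars = list(ss.sequence)
        for i, j in new_pairs:
            x, y = _COMPLEMENT_CHOICES[int(rng.integers(0, 4))]
            chars[i - 1] = x
            chars[j - 1] = y
        seq = "".join(chars)
    return SecondaryStructure(
        name=f"{ss.name}_pk",
        length=ss.length,
        pairs=frozenset(ss.pairs) | new_pairs,
        sequence=seq,
    )


# ---------------------------------------------------------------------------
# toy coordinates

def synthetic_coordinates(ss: SecondaryStructure, seed: int = 0) -> gemmi.Structure:
    """Dummy atomic coordinates: P, C4' and N1 per residue on a helix curve.

    Residue numbering matches ``ss``; the layout is deterministic per seed
    (a seeded phase offsets the curve).  Sufficient for fragment-extraction
    work, with no geometric realism.
    """
    rng = np.random.default_rng(seed)
    phase = float(rng.uniform(0, 2 * np.pi))
    st = gemmi.Structure()
    st.name = ss.name or "synthetic"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    rise, radius, twist = 2.8, 9.0, 2 * np.pi / 11
    for i in range(1, ss.length + 1):
        res = gemmi.Residue()
        res.name = (ss.base(i) or "N")
        res.seqid = gemmi.SeqId(i, " ")
        theta = phase + i * twist
        base = np.array([radius * np.cos(theta), radius * np.sin(theta), i * rise])
        for k, atom_name in enumerate(("P", "C4'", "N1")):
            atom = gemmi.Atom()
            atom.name = atom_name
            atom.element = gemmi.Element(atom_name[0])
            pos = base + k * np.array([0.8, 0.4, 0.2])
            atom.pos = gemmi.Position(*pos)
            atom.occ = 1.0
            atom.b_iso = 10.0
            res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def coordinates_pdb_string(st: gemmi.Structure) -> str:
    """Deterministic PDB text for a structure (same input, same bytes)."""
    return st.make_pdb_string()
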