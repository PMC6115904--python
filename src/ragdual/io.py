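"""Readers, writers and base-pair filters for RNA secondary structures.

Supported formats:

* dot-bracket (``.dbn``): optional ``>name`` header, optional sequence line,
  structure line.  Pseudoknots use multi-level brackets: ``()``, ``[]``,
  ``{}``, ``<>`` and then letter pairs ``Aa``-``Zz``.
* CT: header line starting with the residue count, then six columns
  (index, base, previous, next, pair-or-0, original number).
* BPSEQ: three columns (index, base, pair-or-0).

Readers require strictly increasing integer residue numbers; renumbering of
insertion codes is the caller's concern.  Filters implement canonical-pair
selection (AU/GC Watson-Crick preferred over GU wobble) and the dataset-level
rejection of structures that cannot yield a dual graph of at least two
vertices.
"""

from __future__ import annotations

import logging
from typing import Iterable, List, Sequence, Tuple

from .structure import Pair, SecondaryStructure, StructureError, normalize_base

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "parse_dotbracket",
    "parse_ct",
    "parse_bpseq",
    "write_dotbracket",
    "write_ct",
    "write_bpseq",
    "select_canonical_pairs",
    "filter_canonical_pairs",
    "passes_dataset_filter",
]


class ParseError(ValueError):
    """Malformed secondary-structure file."""


# ---------------------------------------------------------------------------
# dot-bracket

_OPENERS = "([{<" + "".join(chr(c) for c in range(ord("A"), ord("Z") + 1))
_CLOSERS = ")]}>" + "".join(chr(c) for c in range(ord("a"), ord("z") + 1))
_CLOSE_OF = dict(zip(_OPENERS, _CLOSERS))
_LEVEL_OF_OPEN = {c: k for k, c in enumerate(_OPENERS)}
_LEVEL_OF_CLOSE = {c: k for k, c in enumerate(_CLOSERS)}

_SEQ_CHARS = set("ACGUTNRYSWKMBDHVIP acgutnryswkmbdhvip")


def parse_dotbracket(text: str) -> SecondaryStructure:
    """Parse a dot-bracket record (optionally with ``>name`` and sequence lines).

    Multi-level pseudoknot brackets are matched independently per level.
    Raises :class:`ParseError` on unbalanced brackets (naming the level and
    1-based position) or unknown characters.
    """
    name = ""
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if lines and lines[0].startswith(">"):
        name = lines[0][1:].strip()
        lines = lines[1:]
    if not lines:
        raise ParseError("empty dot-bracket record")
    sequence = None
    if len(lines) == 1:
        struct = lines[0]
    else:
        sequence, struct = lines[0], lines[1]
        if not set(sequence) <= _SEQ_CHARS:
            raise ParseError("sequence line contains non-residue characters")
        if len(sequence) != len(struct):
            raise ParseError(
                f"sequence length {len(sequence)} != structure length {len(struct)}"
            )
    stacks: dict[int, list[int]] = {}
    pairs: list[Pair] = []
    for pos, c in enumerate(struct, start=1):
        if c == ".":
            continue
        if c in _LEVEL_OF_OPEN:
            stacks.setdefault(_LEVEL_OF_OPEN[c], []).append(pos)
        elif c in _LEVEL_OF_CLOSE:
            level = _LEVEL_OF_CLOSE[c]
            if not stacks.get(level):
                raise ParseError(
                    f"unbalanced bracket at level {level} "
                    f"(symbol {_OPENERS[level]}{_CLOSERS[level]}): "
                    f"unmatched '{c}' at position {pos}"
                )
            pairs.append((stacks[level].pop(), pos))
        else:
            raise ParseError(f"unknown character {c!r} at position {pos}")
    for level, stack in stacks.items():
        if stack:
            raise ParseError(
                f"unbalanced bracket at level {level} "
                f"(symbol {_OPENERS[level]}{_CLOSERS[level]}): "
                f"unmatched '{_OPENERS[level]}' at position {stack[-1]}"
            )
    return SecondaryStructure(
        name=name, length=len(struct), pairs=frozenset(pairs), sequence=sequence
    )


def _assign_bracket_levels(pairs: Sequence[Pair]) -> dict[Pair, int]:
    """Greedy page assignment: each pair gets the lowest level where it does
    not cross any pair already at that level."""
    levels: dict[Pair, int] = {}
    per_level: list[list[Pair]] = []
    for i, j in sorted(pairs):
        lvl = 0
        while True:
            if lvl == len(per_level):
                per_level.append([])
            crossing = any(
                (k < i < l < j) or (i < k < j < l) for k, l in per_level[lvl]
            )
            if not crossing:
                per_level[lvl].append((i, j))
                levels[(i, j)] = lvl
                break
            lvl += 1
    if per_level and len(per_level) > len(_OPENERS):
        raise ParseError("structure needs more bracket levels than available")
    return levels


def write_dotbracket(ss: SecondaryStructure) -> str:
    """Render a structure as a dot-bracket record (LF endings, no padding)."""
    chars = ["."] * ss.length
    for (i, j), lvl in _assign_bracket_levels(ss.sorted_pairs()).items():
        chars[i - 1] = _OPENERS[lvl]
        chars[j - 1] = _CLOSERS[lvl]
    out = [f">{ss.name}"]
    if ss.sequence is not None:
        out.append(ss.sequence)
    out.append("".join(chars))
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# CT / BPSEQ

def _pairs_from_pair_column(
    rows: List[Tuple[int, str, int]], what: str
) -> frozenset[Pair]:
    """Validate a symmetric index/pair listing and deduplicate to i < j."""
    if not rows:
        raise ParseError(f"no residues in {what} record")
    n = len(rows)
    by_index = {}
    for k, (idx, base, mate) in enumerate(rows, start=1):
        if idx != k:
            raise ParseError(
                f"{what} indices must be strictly increasing from 1 "
                f"(row {k} has index {idx})"
            )
        by_index[idx] = mate
    pairs = set()
    for idx, mate in by_index.items():
        if mate == 0:
            continue
        if mate not in by_index:
            raise ParseError(f"{what} row {idx} pairs with missing residue {mate}")
        if by_index[mate] != idx:
            raise ParseError(
                f"asymmetric pairing in {what}: row {idx} says {mate} "
                f"but row {mate} says {by_index[mate]}"
            )
        if mate == idx:
            raise ParseError(f"{what} row {idx} pairs with itself")
        pairs.add((min(idx, mate), max(idx, mate)))
    return frozenset(pairs)


def parse_ct(text: str) -> SecondaryStructure:
    """Parse a single-record CT file (standard 6-column body)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParseError("empty CT record")
    header = lines[0].split()
    try:
        n = int(header[0])
    except (ValueError, IndexError):
        raise ParseError("CT header must start with the residue count") from None
    name = " ".join(header[1:]) if len(header) > 1 else ""
    body = lines[1:]
    if len(body) != n:
        raise ParseError(f"CT header says {n} residues, body has {len(body)} rows")
    rows: List[Tuple[int, str, int]] = []
    seq = []
    for ln in body:
        f = ln.split()
        if len(f) < 6:
            raise ParseError(f"CT row has {len(f)} columns, expected 6: {ln!r}")
        rows.append((int(f[0]), f[1], int(f[4])))
        seq.append(f[1])
    pairs = _pairs_from_pair_column(rows, "CT")
    return SecondaryStructure(
        name=name, length=n, pairs=pairs, sequence="".join(seq)
    )


def write_ct(ss: SecondaryStructure) -> str:
    pm = ss.partner_map()
    seq = ss.sequence or "N" * ss.length
    out = [f"{ss.length} {ss.name}".rstrip()]
    for i in range(1, ss.length + 1):
        nxt = i + 1 if i < ss.length else 0
        out.append(f"{i} {seq[i - 1]} {i - 1} {nxt} {pm.get(i, 0)} {i}")
    return "\n".join(out) + "\n"


def parse_bpseq(text: str) -> SecondaryStructure:
    """Parse a BPSEQ record (3-column body; ``#`` comment lines skipped)."""
    rows: List[Tuple[int, str, int]] = []
    seq = []
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        f = ln.split()
        if len(f) != 3:
            raise ParseError(f"BPSEQ row has {len(f)} columns, expected 3: {ln!r}")
        rows.append((int(f[0]), f[1], int(f[2])))
        seq.append(f[1])
    pairs = _pairs_from_pair_column(rows, "BPSEQ")
    return SecondaryStructure(
        name="", length=len(rows), pairs=pairs, sequence="".join(seq)
    )


def write_bpseq(ss: SecondaryStructure) -> str:
    pm = ss.partner_map()
    seq = ss.sequence or "N" * ss.length
    out = [f"{i} {seq[i - 1]} {pm.get(i, 0)}" for i in range(1, ss.length + 1)]
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# filters

_WATSON_CRICK = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


def _pair_class(sequence: str, i: int, j: int) -> int:
    """0 = Watson-Crick, 1 = GU wobble, -1 = non-canonical."""
    duo = (normalize_base(sequence[i - 1]), normalize_base(sequence[j - 1]))
    if duo in _WATSON_CRICK:
        return 0
    if duo in _WOBBLE:
        return 1
    return -1


def select_canonical_pairs(
    sequence: str, candidates: Iterable[Pair]
) -> frozenset[Pair]:
    """Resolve a raw candidate pair list to a conflict-free canonical set.

    Non-canonical pairs are dropped.  When a position participates in more
    than one candidate pair, a Watson-Crick pair (AU/GC) wins over a GU
    wobble; remaining conflicts are resolved deterministically in favour of
    the pair with the smaller ``(i, j)``.  Ties between two Watson-Crick
    candidates are logged, since annotated input rarely contains them.
    """
    ranked = []
    for i, j in candidates:
        if i > j:
            i, j = j, i
        cls = _pair_class(sequence, i, j)
        if cls >= 0:
            ranked.append((cls, i, j))
    ranked.sort()
    taken: set[int] = set()
    kept = set()
    for cls, i, j in ranked:
        if i in taken or j in taken:
            if cls == 0:
                logger.debug(
                    "Watson-Crick pair (%d, %d) dropped in favour of an "
                    "earlier Watson-Crick pair at the same position", i, j,
                )
            continue
        taken.add(i)
        taken.add(j)
        kept.add((i, j))
    return frozenset(kept)


def filter_canonical_pairs(ss: SecondaryStructure) -> SecondaryStructure:
    """Keep only canonical (AU, GC, GU) pairs of a structure.

    Pairs-only structures (no sequence) pass through unchanged with a
    warning, since their pairing chemistry cannot be checked.  The operation
    is total and idempotent.
    """
    if ss.sequence is None:
        logger.warning(
            "structure %r has no sequence; canonical filtering skipped", ss.name
        )
        return ss
    return ss.with_pairs(select_canonical_pairs(ss.sequence, ss.pairs))


def passes_dataset_filter(ss: SecondaryStructure) -> Tuple[bool, str]:
    """Dataset-level filter: reject structures whose dual graph has < 2 vertices.

    Returns ``(False, reason)`` with reason ``"no_pairs"``,
    ``"isolated_pairs_only"`` or ``"single_stem"``, else ``(True, "ok")``.
    Canonical filtering is assumed to have been applied already.
    """
    from .graphs import find_stems  # local import: io has no other graph needs

    if not ss.pairs:
        return False, "no_pairs"
    stems = find_stems(ss)
    if len(stems) == 0:
        return False, "isolated_pairs_only"
    if len(stems) == 1:
        return False, "single_stem"
    return True, "ok"
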