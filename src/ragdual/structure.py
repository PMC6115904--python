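"""Residue-level model of an RNA secondary structure.

A secondary structure is a sequence (optional) plus a set of base pairs
``(i, j)`` with ``1 <= i < j <= length`` and at most one partner per
position.  All coordinates throughout the package are 1-based and ranges
are inclusive, following the native convention of CT and BPSEQ files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import FrozenSet, Iterable, Optional, Tuple

Pair = Tuple[int, int]

#: Map from modified-base one-letter codes to the parent base used for
#: canonical-pair checks.  Codes absent from this table are treated as
#: non-canonical partners, never as parse errors.
MODIFIED_BASE_PARENT = {
    "T": "U",  # ribothymidine / 5-methyluridine
    "P": "U",  # pseudouridine
    "I": "G",  # inosine (pairs like G with C)
}


class StructureError(ValueError):
    """Invalid residue/pair-level data."""


def normalize_base(code: str) -> str:
    """Upper-case a residue code and map known modified bases to a parent."""
    c = code.upper()
    return MODIFIED_BASE_PARENT.get(c, c)


@dataclass(frozen=True)
class SecondaryStructure:
    """An RNA chain with its base pairs.

    Parameters
    ----------
    name:
        Free-text label.
    length:
        Number of residues.
    pairs:
        Frozen set of ``(i, j)`` tuples, ``1 <= i < j <= length``, at most
        one partner per position.
    sequence:
        Residue codes (case-insensitive, modified bases allowed) or ``None``
        for pairs-only structures used in graph-level work.
    """

    name: str
    length: int
    pairs: FrozenSet[Pair] = field(default_factory=frozenset)
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length < 0:
            raise StructureError(f"negative length {self.length}")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise StructureError(
                f"sequence length {len(self.sequence)} != length {self.length}"
            )
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= self.length):
                raise StructureError(f"pair ({i}, {j}) outside 1..{self.length}")
            if i in seen or j in seen:
                raise StructureError(f"position in more than one pair near ({i}, {j})")
            seen.add(i)
            seen.add(j)

    # -- convenience -------------------------------------------------------

    def partner_map(self) -> dict[int, int]:
        """Return the symmetric position -> partner mapping."""
        pm: dict[int, int] = {}
        for i, j in self.pairs:
            pm[i] = j
            pm[j] = i
        return pm

    def sorted_pairs(self) -> list[Pair]:
        return sorted(self.pairs)

    def base(self, i: int) -> Optional[str]:
        """Residue code at 1-based position ``i`` (``None`` without sequence)."""
        if self.sequence is None:
            return None
        return self.sequence[i - 1]

    def with_pairs(self, pairs: Iterable[Pair]) -> "SecondaryStructure":
        return replace(self, pairs=frozenset(pairs))

    def has_crossing(self) -> bool:
        """True iff some pairs ``(i, j)``, ``(k, l)`` satisfy ``i < k < j < l``.

        This is the pseudoknot criterion at the base-pair level: intertwined,
        non-nested pairing.
        """
        ps = self.sorted_pairs()
        for a in range(len(ps)):
            i, j = ps[a]
            for b in range(a + 1, len(ps)):
                k, l = ps[b]
                if k >= j:
                    break
                if i < k < j < l:
                    return True
        return False
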