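"""Laplacian spectra and the topology catalog.

Topologies are classified by the eigenvalue spectrum of the graph Laplacian
``L = D - A``, where ``A`` holds edge multiplicities and ``D`` its row sums.
Self loops are ignored for all spectral work, so graphs differing only in
hairpin loops share a topology ID.  For a connected graph the first
eigenvalue is 0 and the second (Fiedler) eigenvalue is positive.

Catalog IDs have the form ``V_n`` where ``V`` is the vertex count and ``n``
is a 1-based rank assigned by lexicographic order of the rounded spectrum
within each vertex count.  Because the historically published RAG numbering
is not derivable from the spectrum ordering alone, an alias table remaps
internal IDs to published ones; aliases for the two-vertex topologies and
the named junction cycles are seeded automatically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.linalg

from .graphs import DualGraph

logger = logging.getLogger(__name__)

__all__ = [
    "CatalogIntegrityError",
    "laplacian",
    "laplacian_from_adjacency",
    "spectrum",
    "spectrum_key",
    "CatalogEntry",
    "TopologyCatalog",
    "assign_topology_id",
    "load_catalog",
    "save_catalog",
    "seed_published_aliases",
]

#: Default absolute per-eigenvalue tolerance for spectral matching.
MATCH_TOL = 1e-6
#: Decimal places kept in catalog spectrum keys.
KEY_DECIMALS = 8


class CatalogIntegrityError(ValueError):
    """Catalog violates uniqueness or schema constraints."""


# ---------------------------------------------------------------------------
# spectra

def laplacian_from_adjacency(a: np.ndarray) -> np.ndarray:
    """``L = D - A`` for a symmetric multiplicity matrix with zero diagonal."""
    a = np.asarray(a, dtype=float)
    a = a - np.diag(np.diag(a))  # self loops are ignored
    return np.diag(a.sum(axis=1)) - a


def laplacian(g: DualGraph) -> np.ndarray:
    """Laplacian of a dual graph; self loops are dropped from A and D."""
    return laplacian_from_adjacency(g.adjacency())


def spectrum(l_matrix: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Ascending real eigenvalues of a symmetric Laplacian.

    Values within ``tol`` of zero are clamped to exactly 0.  Raises
    ``ValueError`` on non-symmetric input.
    """
    l_matrix = np.asarray(l_matrix, dtype=float)
    if l_matrix.ndim != 2 or l_matrix.shape[0] != l_matrix.shape[1]:
        raise ValueError("Laplacian must be square")
    if not np.allclose(l_matrix, l_matrix.T):
        raise ValueError("Laplacian must be symmetric")
    ev = scipy.linalg.eigvalsh(l_matrix)
    ev[np.abs(ev) <= tol] = 0.0
    return ev


def spectrum_key(values: Sequence[float], decimals: int = KEY_DECIMALS) -> Tuple[float, ...]:
    """Rounded ascending spectrum used as a dictionary key; ``-0.0`` folded to ``0.0``."""
    return tuple(round(float(v), decimals) + 0.0 for v in sorted(values))


def graph_spectrum_key(g: DualGraph) -> Tuple[float, ...]:
    return spectrum_key(spectrum(laplacian(g)))


# ---------------------------------------------------------------------------
# catalog

@dataclass(frozen=True)
class CatalogEntry:
    """One topology: ID, vertex count, spectrum key and a representative
    adjacency (upper-triangle multiplicities in row-major order)."""

    id: str
    n_vertices: int
    spectrum: Tuple[float, ...]
    adjacency_upper_triangle: Tuple[int, ...]

    def adjacency(self) -> np.ndarray:
        n = self.n_vertices
        a = np.zeros((n, n), dtype=int)
        k = 0
        for i in range(n):
            for j in range(i + 1, n):
                a[i, j] = a[j, i] = self.adjacency_upper_triangle[k]
                k += 1
        return a


@dataclass
class TopologyCatalog:
    """Ordered topology library with spectral lookup and published-ID aliases."""

    max_vertices: int
    entries: List[CatalogEntry] = field(default_factory=list)
    aliases: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index: Dict[int, Dict[Tuple[float, ...], CatalogEntry]] = {}
        for e in self.entries:
            self._add_to_index(e)

    def _add_to_index(self, e: CatalogEntry) -> None:
        per_n = self._index.setdefault(e.n_vertices, {})
        if e.spectrum in per_n:
            raise CatalogIntegrityError(
                f"duplicate spectrum key for {e.n_vertices} vertices: {e.id} "
                f"vs {per_n[e.spectrum].id}"
            )
        if any(other.id == e.id for other in self.entries if other is not e):
            raise CatalogIntegrityError(f"duplicate catalog id {e.id}")
        per_n[e.spectrum] = e

    def add_entry(self, entry: CatalogEntry) -> None:
        self.entries.append(entry)
        try:
            self._add_to_index(entry)
        except CatalogIntegrityError:
            self.entries.pop()
            raise

    def next_free_n(self, n_vertices: int) -> int:
        return len(self._index.get(n_vertices, {})) + 1

    def lookup(
        self, n_vertices: int, key: Tuple[float, ...], match_tol: float = MATCH_TOL
    ) -> Optional[CatalogEntry]:
        """Entry whose spectrum matches ``key`` component-wise within ``match_tol``."""
        per_n = self._index.get(n_vertices, {})
        hit = per_n.get(key)
        if hit is not None:
            return hit
        arr = np.array(key)
        for e in per_n.values():
            if np.all(np.abs(np.array(e.spectrum) - arr) <= match_tol):
                return e
        return None

    def published_id(self, internal_id: str) -> str:
        return self.aliases.get(internal_id, internal_id)


def assign_topology_id(
    g: DualGraph, cat: TopologyCatalog, match_tol: float = MATCH_TOL
) -> str:
    """Assign a ``V_n`` topology ID to a connected dual graph.

    Outside the catalog's vertex range the vertex count alone is returned
    (the library defines IDs only for 2 to ``max_vertices`` vertices).
    Inside the range an unmatched spectrum returns the sentinel ``"V_new"``
    (e.g. ``"7_new"``); the caller may then append the graph to the catalog
    under the next free ``n``.  Published aliases are applied when present.
    """
    if not g.is_connected():
        raise ValueError("topology IDs are defined for connected graphs only")
    n = g.n_vertices
    if n < 2 or n > cat.max_vertices:
        return str(n)
    entry = cat.lookup(n, graph_spectrum_key(g), match_tol)
    if entry is None:
        return f"{n}_new"
    return cat.published_id(entry.id)


# ---------------------------------------------------------------------------
# persistence

def save_catalog(cat: TopologyCatalog, path: str) -> None:
    """Deterministic JSON dump (sorted keys, fixed spectrum rounding)."""
    payload = {
        "max_vertices": cat.max_vertices,
        "entries": [
            {
                "id": e.id,
                "n_vertices": e.n_vertices,
                "spectrum": [round(v, KEY_DECIMALS) for v in e.spectrum],
                "adjacency_upper_triangle": list(e.adjacency_upper_triangle),
            }
            for e in cat.entries
        ],
        "aliases": dict(sorted(cat.aliases.items())),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1)
        fh.write("\n")


def load_catalog(path: str) -> TopologyCatalog:
    """Load a catalog; duplicate spectrum keys raise :class:`CatalogIntegrityError`."""
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise CatalogIntegrityError(f"corrupted catalog file: {exc}") from exc
    try:
        entries = [
            CatalogEntry(
                id=e["id"],
                n_vertices=int(e["n_vertices"]),
                spectrum=spectrum_key(e["spectrum"]),
                adjacency_upper_triangle=tuple(int(x) for x in e["adjacency_upper_triangle"]),
            )
            for e in payload["entries"]
        ]
        cat = TopologyCatalog(
            max_vertices=int(payload["max_vertices"]),
            entries=entries,
            aliases=dict(payload.get("aliases", {})),
        )
    except (KeyError, TypeError) as exc:
        raise CatalogIntegrityError(f"corrupted catalog file: {exc}") from exc
    return cat


# ---------------------------------------------------------------------------
# published aliases

def _find_by_adjacency(
    cat: TopologyCatalog, upper: Tuple[int, ...], n: int
) -> Optional[CatalogEntry]:
    a = np.zeros((n, n))
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            a[i, j] = a[j, i] = upper[k]
            k += 1
    key = spectrum_key(spectrum(laplacian_from_adjacency(a)))
    return cat.lookup(n, key)


def seed_published_aliases(cat: TopologyCatalog) -> None:
    """Seed aliases for topologies with historically fixed published IDs.

    The two-vertex topologies are 2_1/2_2/2_3 (single, double, triple edge)
    and the simple k-cycles are the published k-way junction IDs: 3_5,
    4_19, 5_2, 6_2 and 7_2389.  Entries outside ``max_vertices`` are
    skipped.  No-op entries (internal ID already equal to the published
    one) are recorded all the same, keeping the mapping explicit.
    """
    published_cycles = {3: "3_5", 4: "4_19", 5: "5_2", 6: "6_2", 7: "7_2389"}

    def cycle_upper(n: int) -> Tuple[int, ...]:
        upper = []
        for i in range(n):
            for j in range(i + 1, n):
                adjacent = j - i == 1 or (i == 0 and j == n - 1)
                upper.append(1 if adjacent else 0)
        return tuple(upper)

    for mult in (1, 2, 3):
        e = _find_by_adjacency(cat, (mult,), 2)
        if e is not None:
            cat.aliases[e.id] = f"2_{mult}"
    for n, pub in published_cycles.items():
        if n > cat.max_vertices:
            continue
        e = _find_by_adjacency(cat, cycle_upper(n), n)
        if e is not None:
            cat.aliases[e.id] = pub
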