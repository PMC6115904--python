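"""Exhaustive enumeration of RNA-valid dual-graph topologies.

Candidate topologies are connected multigraphs without self loops, with at
most three parallel edges between any vertex pair, maximum degree four, and
a degree sequence achievable by a linear RNA chain: exactly two vertices of
odd degree, or none and at least one vertex of degree two (the 5'/3' end
helix).  Self loops never need enumerating because they are invisible to
the Laplacian spectrum that defines topology identity.

The search is a degree-pruned backtracking over the upper-triangle
multiplicities, so completeness is guaranteed; this replaces probabilistic
graph growing, whose libraries were later found to miss topologies at
higher vertex counts.  Deduplication is spectral by default (cospectral
non-isomorphic graphs are merged, and logged when the isomorphism oracle is
consulted) or by canonical certificate for verification.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Iterator, List, Tuple

import numpy as np
import scipy.linalg

from .spectral import (
    KEY_DECIMALS,
    CatalogEntry,
    TopologyCatalog,
    laplacian_from_adjacency,
    seed_published_aliases,
    spectrum_key,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateGraph",
    "enumerate_candidates",
    "enumerate_topologies",
    "build_catalog",
    "canonical_certificate",
]

MAX_EDGE_MULTIPLICITY = 3
MAX_DEGREE = 4


@dataclass(frozen=True)
class CandidateGraph:
    """An enumerated topology: vertex count plus upper-triangle multiplicities."""

    n_vertices: int
    upper_triangle: Tuple[int, ...]

    def adjacency(self) -> np.ndarray:
        n = self.n_vertices
        a = np.zeros((n, n))
        k = 0
        for i in range(n):
            for j in range(i + 1, n):
                a[i, j] = a[j, i] = self.upper_triangle[k]
                k += 1
        return a

    def degrees(self) -> List[int]:
        return self.adjacency().sum(axis=1).astype(int).tolist()

    def spectrum_key(self) -> Tuple[float, ...]:
        ev = scipy.linalg.eigvalsh(laplacian_from_adjacency(self.adjacency()))
        return spectrum_key(ev)


def _pair_order(n: int) -> List[Tuple[int, int]]:
    return list(itertools.combinations(range(n), 2))


def _connected(n: int, pairs: List[Tuple[int, int]], mult: List[int]) -> bool:
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for k, (a, b) in enumerate(pairs):
        if mult[k]:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    return len({find(v) for v in range(n)}) == 1


def rna_degree_pattern_ok(degrees: List[int]) -> bool:
    """Achievability form of the RNA end-helix degree constraint
    (see :func:`ragdual.graphs.is_valid_rna_degree_pattern`)."""
    if max(degrees) > MAX_DEGREE:
        return False
    odd = sum(1 for d in degrees if d % 2)
    return odd == 2 or (odd == 0 and min(degrees) <= 2)


def enumerate_candidates(n_vertices: int) -> Iterator[CandidateGraph]:
    """Yield every valid candidate graph on ``n_vertices`` labelled vertices.

    Backtracking over upper-triangle multiplicities in lexicographic pair
    order.  Pruning: partial degrees never exceed 4; once all edges at a
    vertex are decided its degree is final, so it must be >= 1 (isolated
    vertices can never reconnect) and the number of finalized odd-degree
    vertices may never exceed two.  Connectivity and the full degree
    pattern are checked on completion.
    """
    n = n_vertices
    if n < 2:
        raise ValueError("enumeration needs at least 2 vertices")
    pairs = _pair_order(n)
    m = len(pairs)
    last_touch = [max(k for k, (a, b) in enumerate(pairs) if v in (a, b))
                  for v in range(n)]
    finalized_at: List[List[int]] = [[] for _ in range(m)]
    for v in range(n):
        finalized_at[last_touch[v]].append(v)

    deg = [0] * n
    mult = [0] * m
    out: List[CandidateGraph] = []

    def backtrack(k: int, odd_final: int) -> None:
        if k == m:
            if _connected(n, pairs, mult) and rna_degree_pattern_ok(deg):
                out.append(CandidateGraph(n, tuple(mult)))
            return
        a, b = pairs[k]
        cap = min(MAX_EDGE_MULTIPLICITY, MAX_DEGREE - deg[a], MAX_DEGREE - deg[b])
        for v in range(cap + 1):
            mult[k] = v
            deg[a] += v
            deg[b] += v
            of = odd_final
            ok = True
            for u in finalized_at[k]:
                if deg[u] == 0:
                    ok = False
                    break
                if deg[u] % 2:
                    of += 1
            if ok and of <= 2:
                backtrack(k + 1, of)
            deg[a] -= v
            deg[b] -= v
        mult[k] = 0

    backtrack(0, 0)
    yield from out


def enumerate_topologies(
    n_vertices: int, dedup: str = "spectral"
) -> List[CandidateGraph]:
    """All distinct topologies on ``n_vertices`` vertices.

    ``dedup="spectral"`` keeps one representative per Laplacian spectrum
    (cospectral non-isomorphic graphs are merged); ``dedup="isomorphism"``
    keeps one per multigraph isomorphism class.  Representatives are
    returned in lexicographic order of spectrum key (then certificate),
    which is what defines the catalog numbering.
    """
    if dedup not in ("spectral", "isomorphism"):
        raise ValueError(f"unknown dedup mode {dedup!r}")
    if n_vertices > 9:
        warnings.warn(
            f"enumeration at {n_vertices} vertices is unsupported territory "
            "and may take very long", RuntimeWarning, stacklevel=2,
        )
    reps: Dict[Tuple, CandidateGraph] = {}
    for g in enumerate_candidates(n_vertices):
        skey = g.spectrum_key()
        key = skey if dedup == "spectral" else (skey, canonical_certificate(g))
        if key not in reps:
            reps[key] = g
    return [reps[k] for k in sorted(reps)]


def build_catalog(
    max_vertices: int = 6,
    dedup: str = "spectral",
    check_cospectral: bool = False,
    seed_aliases: bool = True,
) -> TopologyCatalog:
    """Enumerate all topologies for 2..``max_vertices`` vertices as a catalog.

    ``n`` in each ``V_n`` ID is the 1-based rank of the spectrum key within
    its vertex count.  With ``check_cospectral`` the canonical-certificate
    oracle verifies every spectral merge and logs genuinely cospectral
    non-isomorphic pairs (they stay merged, as in spectral deduplication).
    """
    cat = TopologyCatalog(max_vertices=max_vertices)
    for n in range(2, max_vertices + 1):
        if check_cospectral:
            by_spec: Dict[Tuple, List[CandidateGraph]] = {}
            for g in enumerate_candidates(n):
                by_spec.setdefault(g.spectrum_key(), []).append(g)
            reps = []
            for skey in sorted(by_spec):
                certs = {canonical_certificate(g): g for g in by_spec[skey]}
                if len(certs) > 1:
                    logger.info(
                        "cospectral non-isomorphic graphs merged at %d vertices: "
                        "spectrum %s covers %d isomorphism classes",
                        n, skey, len(certs),
                    )
                reps.append(by_spec[skey][0])
        else:
            reps = enumerate_topologies(n, dedup=dedup)
        for rank, g in enumerate(reps, start=1):
            cat.add_entry(
                CatalogEntry(
                    id=f"{n}_{rank}",
                    n_vertices=n,
                    spectrum=g.spectrum_key(),
                    adjacency_upper_triangle=g.upper_triangle,
                )
            )
    if seed_aliases:
        seed_published_aliases(cat)
    return cat


# ---------------------------------------------------------------------------
# isomorphism oracle

def canonical_certificate(g: CandidateGraph) -> Tuple[int, ...]:
    """Minimum upper-triangle encoding over all vertex relabelings.

    Two candidate graphs are isomorphic as multigraphs iff their
    certificates are equal.  Permutations are restricted to those mapping
    vertices onto vertices of equal degree, which keeps n <= 9 feasible.
    """
    n = g.n_vertices
    a = g.adjacency().astype(int)
    degs = a.sum(axis=1)
    by_deg: Dict[int, List[int]] = {}
    for v in range(n):
        by_deg.setdefault(int(degs[v]), []).append(v)
    classes = [by_deg[d] for d in sorted(by_deg)]

    best: Tuple[int, ...] | None = None
    for parts in itertools.product(*(itertools.permutations(c) for c in classes)):
        # inv[new_label] = original vertex; new labels are blocked by degree
        inv = [v for p in parts for v in p]
        key = tuple(
            a[inv[i], inv[j]] for i in range(n) for j in range(i + 1, n)
        )
        if best is None or key < best:
            best = key
    assert best is not None
    return best
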