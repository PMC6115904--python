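import numpy as np
import pytest

from ragdual import build_catalog
from ragdual.graphs import DualGraph
from ragdual.synthetic import insert_h_pseudoknot, random_nested_structure


@pytest.fixture(scope="session")
def catalog():
    """Exhaustive topology catalog up to 5 vertices, with published aliases."""
    return build_catalog(max_vertices=5)


def make_nested(seed, n_stems=None, n_residues=None):
    rng = np.random.default_rng(seed)
    if n_stems is None:
        n_stems = int(rng.integers(2, 6))
    if n_residues is None:
        n_residues = 30 + 22 * n_stems
    return random_nested_structure(n_residues, n_stems, seed)


def make_pseudoknotted(seed):
    """A nested fixture with one H-type pseudoknot inserted (retries seeds
    whose random layout offers no insertion site)."""
    for offset in range(40):
        ss = make_nested(seed + 100_000 * (offset + 1))
        try:
            return insert_h_pseudoknot(ss, seed)
        except ValueError:
            continue
    raise RuntimeError(f"no insertable fixture found for seed {seed}")


def random_multigraph(seed, max_vertices=7):
    """A random connected multigraph (multiplicities 1-3, no self loops);
    not necessarily RNA-valid.  Used for graph-algorithm oracle tests."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, max_vertices + 1))
    edge_mult = {}
    # random spanning tree keeps it connected
    for v in range(1, n):
        u = int(rng.integers(0, v))
        edge_mult[(u, v)] = int(rng.integers(1, 4))
    extra = int(rng.integers(0, n + 1))
    for _ in range(extra):
        u, v = sorted(rng.choice(n, size=2, replace=False).tolist())
        key = (int(u), int(v))
        edge_mult[key] = min(3, edge_mult.get(key, 0) + int(rng.integers(1, 4)))
    self_loops = {}
    for v in range(n):
        if rng.random() < 0.2:
            self_loops[v] = 1
    return DualGraph(n_vertices=n, edge_mult=edge_mult, self_loops=self_loops)


def relabel(g: DualGraph, perm):
    """Vertex-relabelled copy of a dual graph (stems/strands dropped)."""
    return DualGraph(
        n_vertices=g.n_vertices,
        edge_mult={
            (min(perm[u], perm[v]), max(perm[u], perm[v])): m
            for (u, v), m in g.edge_mult.items()
        },
        self_loops={perm[v]: c for v, c in g.self_loops.items()},
    )
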