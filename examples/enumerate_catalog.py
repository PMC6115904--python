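"""Exhaustively enumerate dual-graph topologies and save a catalog.

Candidate topologies are connected multigraphs with up to three parallel
edges per vertex pair, maximum degree four and an RNA-achievable degree
sequence; one representative per Laplacian spectrum is kept.  The counts
printed per vertex number are complete: the search is a degree-pruned
backtracking, not probabilistic growing.
"""

from collections import Counter

from ragdual import build_catalog, save_catalog

cat = build_catalog(max_vertices=5)
counts = Counter(e.n_vertices for e in cat.entries)
print("vertices  topologies")
for n in sorted(counts):
    print(f"{n:8d}  {counts[n]}")
print(f"published-ID aliases: {cat.aliases}")
save_catalog(cat, "catalog.json")
print("catalog written to catalog.json")
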