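# Methods

## The dual-graph model

An RNA secondary structure is a set of base pairs `(i, j)` (1-based,
`i < j`, one partner per position) over a chain of length `L`.  The dual
graph coarse-grains it by four rules:

1. a **helix** with at least two stacked canonical pairs (AU, GC, GU) is a
   vertex;
2. each **loop strand** between two helices is an edge — with or without
   residues, so two helices directly adjacent along the backbone are still
   joined by a (zero-length) edge;
3. an **uninterrupted hairpin loop** is a self loop on its helix;
4. unpaired residues or helical ends at the 5′/3′ **termini** are not
   represented.

Single-residue bulges and 1×1 internal loops are *merged*: the two flanking
helices become one vertex.  Merging (rather than suppressing the edge
between two distinct vertices) is what preserves the degree invariant
below; it is applied transitively, only for the exact gap patterns
(1,0), (0,1) and (1,1) with unpaired gap residues, and only when the two
runs are directly nested.  A 2-nt bulge does not merge.  The alternative
reading (keep two vertices, drop the connecting strand) breaks the degree
invariant and is not implemented.

**Degree invariant.**  Walking the backbone, every helix is entered and
left twice, so it touches exactly four loop strands — counting a self loop
twice — except the end helix (or helices): if the 5′ and 3′ termini lie on
one helix it has two strands, otherwise the two end helices have three
each.  Every dual graph of a linear chain therefore has degree sequence
`(4, …, 4, 2)` or `(4, …, 4, 3, 3)` with self loops counted twice.  This
is checked literally on built graphs and used as the feasibility filter in
enumeration.

## Spectral topology identity

Topologies are identified by the spectrum of the Laplacian `L = D − A`,
where `A` holds edge multiplicities with a zero diagonal and `D` its row
sums.  **Self loops are dropped entirely from both `A` and `D`**: two
structures that differ only in hairpin loops have the same topology, which
is also why self loops never need enumerating.  For a connected graph
`λ₁ = 0` and the Fiedler value `λ₂ > 0`.

Numerical choices: eigenvalues come from `scipy.linalg.eigvalsh`; values
within `1e−9` of zero are clamped to 0; catalog keys round the spectrum to
8 decimals; spectral matching uses an absolute per-eigenvalue tolerance of
`1e−6`.  Integer Laplacians of ≤ 9-vertex graphs have spectra separated by
far more than these tolerances, so the specific values are uncritical.

Catalog IDs are `V_n` with `n` the 1-based rank of the spectrum key in
lexicographic order within each vertex count.  This ordering is
deterministic but not guaranteed to reproduce the historically published
RAG numbering, so a user-extendable alias table remaps internal IDs to
published ones.  Aliases are pre-seeded where the published ID is fixed by
well-known motifs: the three 2-vertex topologies (`2_1` single edge, `2_2`
double edge/internal loop, `2_3` triple edge/pseudoknot — these coincide
with the internal ranks) and the k-way junction cycles `3_5`, `4_19`,
`5_2`, `6_2`, `7_2389`.  Graphs with < 2 or > `max_vertices` vertices get
a vertex-count-only label; an in-range graph whose spectrum is absent from
the catalog gets the sentinel `V_new` and may be appended under the next
free rank.

Cospectral collisions (non-isomorphic graphs with equal spectra) first
appear at 5 vertices (two pairs: 110 isomorphism classes, 108 spectra).
Spectral deduplication merges them — the library convention — and
`build_catalog(check_cospectral=True)` logs every merge detected by the
canonical-certificate oracle; `dedup="isomorphism"` keeps them separate
for diagnostics.

## Exhaustive enumeration

Candidates are connected multigraphs on `n` labelled vertices with pair
multiplicities 0–3, no self loops, maximum degree 4, and the achievability
form of the degree invariant: since a self loop raises a topology-level
degree by 2, the literal pattern is reachable iff either exactly two
vertices have odd degree, or none do and at least one vertex has degree
≤ 2 (the end helix).  The search backtracks over upper-triangle
multiplicities in lexicographic pair order, pruning when a partial degree
exceeds 4, when a vertex's degree is finalized at 0, or when more than two
finalized vertices have odd degree; connectivity is checked at the leaves.
Completeness is therefore guaranteed, unlike probabilistic graph growing.
The multiplicity cap of 3 loses nothing: a multiplicity-4 pair saturates
both endpoints, which either disconnects the rest or produces the all-even
degree-4 sequence excluded by the invariant.

Counts with spectral deduplication: 3, 8, **29**, 108, 496 for 2–6
vertices (seconds for ≤ 5; ≈ 10 s for 6 on one CPU).  The historical
library reports 3, 8, **30**, 108, 494.  At 3 and 5 vertices the counts
agree exactly; at 6 the exhaustive count exceeds the grown library, as
expected from grown libraries later found incomplete at 7 and 9 vertices.
At 4 vertices both spectral and isomorphism deduplication (verified with
an independent edge-colored VF2 check) give 29, and relaxing the degree
pattern overshoots everywhere (9/32/114 without the end-helix condition),
so the library's 30th entry must violate the degree constraint that
defines the class: the three excluded 4-vertex graphs are all 4-regular,
and a 4-regular topology admits no end helix.  We report the computed 29.

The isomorphism oracle is a minimum-adjacency canonical certificate over
degree-class-preserving relabelings — exact for multigraphs and feasible
to 9 vertices.

## Partitioning

Articulation points and biconnected components are computed with an
iterative Hopcroft–Tarjan DFS in which every parallel edge instance has
its own identity: a second instance to the DFS parent is a back edge, so
double/triple edges are never bridges.  Bridges are emitted as 2-vertex
single-edge blocks (`2_1`), the standard biconnected-component semantics.
Self loops travel with their vertex as metadata: they never create
articulation points, never affect block boundaries, are excluded from the
pseudoknot degree test, and are invisible to the block's topology ID.
Articulation vertices appear in every block they join.  Blocks are checked
against two independent oracles (brute-force vertex deletion and maximal
biconnected induced subgraphs; networkx on a parallel-edge-subdivided
simple graph) on hundreds of seeded random multigraphs.

A block is classified **pseudoknot** iff some vertex has summed incident
edge multiplicity ≥ 3 within the block, self loops excluded.  On the
synthetic fixtures this flag agrees with the residue-level crossing
oracle: nested chains never produce a flagged block, and every chain with
an inserted crossing produces at least one.

## Fragments

A block's residue footprint is the union of its member stems' strand
ranges, the residues of loop strands realizing its edges, and the hairpin
loops of its members, merged into maximal ranges (backbone-adjacent ranges
coalesce).  An edge between two block members always belongs to that block
because two blocks share at most one vertex.  Residues of a shared
articulation stem are duplicated into every adjacent block's fragment so
each fragment is self-contained; dangling termini are excluded, as they
are not part of the graph.  Extraction keeps original residue numbering,
records missing residues as gaps with a warning, accepts PDB/mmCIF via
gemmi and writes PDB.  Catalogs group fragments per topology; graphs
beyond the catalog range pool under `V>=10`.

## Synthetic data

`random_nested_structure(n_residues, n_stems, seed)` samples a random
ordered forest of stems and realizes it with helix lengths of 2–4 bp,
hairpin loops of 3–6 nt, sibling gaps of 0–2 nt and nesting gaps of 0–3 nt
adjusted so no two distinct stems satisfy the merge geometry; leftover
residues become dangling termini, and paired positions get complementary
bases.  These sizes are ordinary for the small/medium RNAs the
representative structure sets contain; the generator guarantees the
requested vertex count and the absence of crossings, which is what the
invariant tests rely on.  `insert_h_pseudoknot` adds a 2-bp stem pairing
hairpin-loop residues (≥ 4-nt loop) with ≥ 4 consecutive unpaired
residues downstream, keeping one unpaired residue of margin on each side
so the new helix neither stacks onto nor merges with existing ones; the
new pairs cross the hairpin's closing stem by construction.  Property
tests run on 200 structures per condition with stem counts 2–5 (plus one
inserted pseudoknot helix), sizes at which the exhaustive catalog covers
every reachable whole-graph topology.

What the generator does **not** emulate: non-canonical pairing, modified
bases in context, multi-chain complexes, kissing-loop and more complex
pseudoknot geometries beyond H-type insertion, and any thermodynamic
plausibility.  Passing tests therefore demonstrate the graph-level
machinery, not fidelity to experimentally annotated 2D structures; on real
annotations the canonical-pair and dataset filters do the corresponding
clean-up.  The toy coordinates are three atoms per residue on a
deterministic curve — sufficient for exercising extraction bookkeeping,
with no geometric realism.

## Degenerate inputs and edge handling

Pairs-only structures (no sequence) pass the canonical filter unchanged
with a warning.  Structures reducing to < 2 vertices are rejected by the
dataset filter with a reason (`no_pairs`, `isolated_pairs_only`,
`single_stem`); a single-vertex graph partitions to an empty block list
with a warning and carries a vertex-count-only label.  When two candidate
pairs conflict at a position, Watson–Crick beats wobble and remaining ties
keep the smaller `(i, j)` deterministically (logged — annotated input
rarely contains WC–WC conflicts).  Unknown residue codes are treated as
non-canonical partners, never parse errors; a small table maps common
modified bases (ribothymidine, pseudouridine, inosine) to parent bases.

## Known limitations

* The published `V_n` numbering beyond the seeded aliases is not
  reproduced; supply an alias table to align with an external library.
* Enumeration beyond 9 vertices is unsupported (it warns and will be
  slow); 7 vertices takes minutes, not seconds.
* Recursive sub-partitioning of pseudoknot blocks into pseudoknot-free
  parts and isolated pseudoknots is out of scope, as are tree graphs,
  base-pair inference from 3D coordinates, and 3D clustering of fragments.
* Multi-chain input is not combined into one graph; each chain is
  processed independently.
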