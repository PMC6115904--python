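"""Parse a dot-bracket structure and build its dual graph.

The H-type pseudoknot below pairs hairpin-loop residues with downstream
residues, so its two helices are joined by three loop strands: the
hallmark triple-edge dual graph that tree graphs cannot represent.
"""

from ragdual import degree_sequence, dual_graph_from_structure, find_stems, parse_dotbracket

record = """>H-type pseudoknot
GGGGAACCCCAAAUUUUAAGGGG
((((..[[[[...))))..]]]]
"""

ss = parse_dotbracket(record)
stems = find_stems(ss)
g = dual_graph_from_structure(ss)

print(f"{ss.name}: {ss.length} nt, {len(ss.pairs)} base pairs")
for s in stems:
    print(f"  stem {s.index}: 5' {s.five_prime_range}  3' {s.three_prime_range}  "
          f"{len(s.pairs)} bp")
print(f"dual graph: {g.n_vertices} vertices, edges {g.edge_mult}, "
      f"self loops {g.self_loops}")
print(f"degree sequence (self loops counted twice): {degree_sequence(g)}")
# Two vertices joined by a triple edge, degrees (3, 3): the two end helices
# of a chain always have degree 3 (or one helix of degree 2), never 4.
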