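"""Partition dual graphs into non-separable blocks.

Articulation points cut the graph into biconnected blocks; junction cycles
and pseudoknot multi-edges always stay inside one block.  A block is a
pseudoknot iff some vertex has three or more incident edges in the block
(self loops not counted).
"""

from ragdual import build_catalog, parse_dotbracket, partition_structure

cat = build_catalog(max_vertices=5)

structures = {
    "H-type pseudoknot": "((((..[[[[...))))..]]]]",
    "internal loop": "((..((...))..))",
    "3-way junction": "((..((...))((...))..))",
    "hairpin + 4-way junction": "((...))((..((...))((...))((...))..))",
}
for label, text in structures.items():
    blocks = partition_structure(parse_dotbracket(text), cat)
    print(f"{label}:")
    for b in blocks:
        kind = "pseudoknot" if b.is_pseudoknot else "no pseudoknot"
        print(f"  block {b.vertices} -> {b.topology_id} ({kind})")
# 2_3 is the two-helix pseudoknot, 2_2 two stems with an internal loop,
# 3_5 / 4_19 the 3- and 4-way junction cycles, 2_1 two connected stems.
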