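"""Encode every carbon of caffeine with the eight-integer neighbor label.

Each label lists up to four bonded heavy atoms (element codes: C=7, N=17,
O=19, anything else 32) and the four aligned bond orders; hydrogens are
zeroed out, so the bond orders of a CH3 carbon sum to 1.
"""

from nmrsubstruct.neighbor_encoding import encode_atom
from nmrsubstruct.synthetic_data import case_study_graph

graph = case_study_graph("caffeine")
carbons = [i for i, el in graph.atoms if el == "C"]
print(f"caffeine: {len(carbons)} carbon atoms\n")
for idx in carbons:
    label = encode_atom(graph, idx)
    print(f"  atom {idx:2d}: ({label})   bond-order sum {label.bond_sum}")

print(
    "\nEach line is one carbon's one-bond environment; identical lines are"
    "\nchemically equivalent carbons, which is why the eight carbons map to"
    "\nfewer distinct substructure classes."
)
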