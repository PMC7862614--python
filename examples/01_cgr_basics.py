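"""Condensed graphs of reaction: compose, inspect, serialize.

Builds a generalized Suzuki coupling from a mapped reaction SMILES, merges
it into a single CGR, and prints the dynamic bonds and the SMILES/CGR
string.
"""

from cgrgen import compose_cgr, decompose_cgr, parse_reaction_smiles
from cgrgen.smiles import write_reaction_smiles, write_smiles_cgr

line = "[B:1][C:2].[C:3][Br:4]>>[B:1].[C:2][C:3].[Br:4]"
rxn = parse_reaction_smiles(line)
cgr = compose_cgr(rxn)

print("reaction:", line)
print("dynamic bonds (reactant order -> product order):")
for (i, j), (ro, po) in sorted(cgr.dynamic_bonds().items()):
    a, b = cgr.atoms[i].element, cgr.atoms[j].element
    print(f"  {a}{i}-{b}{j}: {ro or '.'} -> {po or '.'}")
print("SMILES/CGR:", write_smiles_cgr(cgr))
print("decomposed:", write_reaction_smiles(decompose_cgr(cgr)))
# Three dynamic bonds: the B-C and C-Br bonds break, the new C-C bond forms.
# The string packs the whole transformation into one molecule-like line.
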