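"""Hydrogen bookkeeping, water balancing and additive enthalpy.

Reproduces the implicit-hydrogen pathology of sketchily recorded couplings:
an amide-for-halide coupling whose products carry two extra hydrogens, the
single-water correction that balances it, and a bond-energy enthalpy
estimate.
"""

from cgrgen import (
    balance_with_water,
    estimate_enthalpy,
    heavy_atom_balance,
    hydrogen_disbalance,
    parse_reaction_smiles,
)
from cgrgen.smiles import write_reaction_smiles

# atom-mapped so the CGR (and hence the enthalpy sum) can be composed
line = (
    "[C:1][C:2](=[O:3])[N:4][C:5][c:6]1[cH:7][cH:8][cH:9][cH:10][cH:11]1."
    "[O:12][B:13]([O:14])[c:15]1[cH:16][cH:17][cH:18][cH:19][cH:20]1"
    ">>[C:1][C:2](=[O:3])-[c:15]1[cH:16][cH:17][cH:18][cH:19][cH:20]1."
    "[N:4][C:5][c:6]1[cH:7][cH:8][cH:9][cH:10][cH:11]1.[O:12][B:13][O:14]"
)
rxn = parse_reaction_smiles(line)
print("hydrogen disbalance:", hydrogen_disbalance(rxn))   # +2
print("heavy-atom balance:", heavy_atom_balance(rxn) or "balanced")

balanced = balance_with_water(rxn)
print("after water correction:", write_reaction_smiles(balanced, with_maps=False))
print("hydrogen disbalance now:", hydrogen_disbalance(balanced))  # 0

est = estimate_enthalpy(balanced)
print(f"additive dH = {est.delta_h:+.0f} kJ/mol "
      f"({'exothermic' if est.exothermic else 'endothermic'})")
print("bonds broken:", est.bonds_broken)
print("bonds formed:", est.bonds_formed)
# The +2 means the decoded string capped two broken bonds with hydrogens;
# adding H2O as a formal base and hydroxylating boron restores stoichiometry.
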