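"""Built-in catalogs of simplified Suzuki-type coupling patterns.

Two small curated sets of simplified reactions (general reactivity
patterns written as minimal reaction SMILES), used as worked examples and
reference inputs:

* ``NEW_RC_PATTERNS`` — eleven couplings whose reaction centers explore
  unusual partner/leaving-group combinations around boron (C-N, C-O, C-S,
  C-Si bond formation, O-I and S-Br leaving groups, and one boron-bromine
  substitution that is not a coupling at all);
* ``KNOWN_RC_NEW_ENV_PATTERNS`` — three water-assisted couplings sharing
  the classical B-C cleavage / C-C formation center but with O, I and Br
  leaving groups on an sp3/acyl carbon; their mapped forms (evident
  template correspondence) are provided for CGR composition.

All strings use implicit-hydrogen completion: every fragment is a valid
molecule once hydrogens fill the open valences.
"""

# unmapped simplified reactions, one per line: reactants > > products
NEW_RC_PATTERNS = (
    "O.BC.N >  > OB.CN",
    "O.BC.OI >  > OB.CO.I",
    "O.BC.CS >  > OB.CC.S",
    "O.BC.CN >  > OB.CC",
    "O.BC.CF >  > OB.CC.F",
    "O.BC.[Si]S >  > OB.C[Si].S",
    "O.BC.BrN >  > BO.CBr.N",
    "O.BC.[Si]Br >  > OB.C[Si].Br",
    "O.BC.[Si]Br >  > OB.C[Si].Br",
    "O.BC.SBr >  > OB.CS.Br",
    "O.BC.O[Si] >  > OB.CO.[Si]",
)

KNOWN_RC_NEW_ENV_PATTERNS = (
    "BC.O.CO >  > O.CC.BO",
    "BC.O.CI >  > I.CC.BO",
    "BC.O.CBr >  > Br.CC.BO",
)

# the same three patterns with atom maps assigned by the evident Suzuki
# template: B1-C2 cleaved, C2-C4 formed, C4-L5 cleaved, B1-O3 formed (water
# O3 delivers the hydroxyl to boron, L5 leaves)
KNOWN_RC_NEW_ENV_MAPPED = (
    "[B:1][C:2].[O:3].[C:4][O:5]>>[O:5].[C:2][C:4].[B:1][O:3]",
    "[B:1][C:2].[O:3].[C:4][I:5]>>[I:5].[C:2][C:4].[B:1][O:3]",
    "[B:1][C:2].[O:3].[C:4][Br:5]>>[Br:5].[C:2][C:4].[B:1][O:3]",
)
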