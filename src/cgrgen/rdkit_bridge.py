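"""Conversion between MoleculeGraph and RDKit molecules.

Used for the standard chemistry steps the package does not reimplement:
aromaticity perception, functional-group normalization and SMARTS
substructure matching.  The CGR layer itself never passes through RDKit
(dynamic bonds have no RDKit representation).
"""

from __future__ import annotations

from rdkit import Chem
from rdkit.Chem.MolStandardize import rdMolStandardize

from .graphs import AtomState, MoleculeGraph

_BOND_TO_RDKIT = {
    "-": Chem.BondType.SINGLE,
    "=": Chem.BondType.DOUBLE,
    "#": Chem.BondType.TRIPLE,
    ":": Chem.BondType.AROMATIC,
}
_BOND_FROM_RDKIT = {v: k for k, v in _BOND_TO_RDKIT.items()}


def to_rdkit(mol: MoleculeGraph, sanitize: bool = True) -> Chem.Mol:
    """Convert to an RDKit molecule; raises on sanitization failure."""
    rw = Chem.RWMol()
    for atom, mid in zip(mol.atoms, mol.map_ids):
        a = Chem.Atom(atom.element)
        a.SetFormalCharge(atom.charge)
        a.SetIsAromatic(atom.aromatic)
        if atom.radical:
            a.SetNumRadicalElectrons(1)
        if mid is not None:
            a.SetAtomMapNum(mid)
        rw.AddAtom(a)
    for (i, j), order in mol.bonds.items():
        rw.AddBond(i, j, _BOND_TO_RDKIT[order])
        if order == ":":
            rw.GetBondBetweenAtoms(i, j).SetIsAromatic(True)
    out = rw.GetMol()
    if sanitize:
        Chem.SanitizeMol(out)
    return out


def from_rdkit(rdmol: Chem.Mol) -> MoleculeGraph:
    """Convert back; implicit hydrogens are dropped (recomputed on demand)."""
    mol = MoleculeGraph()
    for a in rdmol.GetAtoms():
        mol.add_atom(
            AtomState(
                element=a.GetSymbol(),
                charge=a.GetFormalCharge(),
                radical=a.GetNumRadicalElectrons() > 0,
                aromatic=a.GetIsAromatic(),
            ),
            map_id=a.GetAtomMapNum() or None,
        )
    for b in rdmol.GetBonds():
        order = "-" if b.GetIsAromatic() is False else None
        bt = b.GetBondType()
        if b.GetIsAromatic() or bt == Chem.BondType.AROMATIC:
            order = ":"
        else:
            order = _BOND_FROM_RDKIT.get(bt)
            if order is None:
                raise ValueError(f"unsupported bond type {bt}")
        mol.add_bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order)
    return mol


def aromatize(mol: MoleculeGraph) -> MoleculeGraph:
    """Perceive aromaticity (Kekulé input becomes the aromatic form)."""
    return from_rdkit(to_rdkit(mol, sanitize=True))


_NORMALIZER = None


def normalize_groups(mol: MoleculeGraph) -> MoleculeGraph:
    """Apply functional-group normal forms (nitro, azide, sulfoxide, ...).

    Delegates to the RDKit standardizer's default transform list.
    """
    global _NORMALIZER
    if _NORMALIZER is None:
        _NORMALIZER = rdMolStandardize.Normalizer()
    rdmol = to_rdkit(mol, sanitize=True)
    normal = _NORMALIZER.normalize(rdmol)
    Chem.SanitizeMol(normal)
    return from_rdkit(normal)


def matches_smarts(mol: MoleculeGraph, smarts: str) -> bool:
    query = Chem.MolFromSmarts(smarts)
    if query is None:
        raise ValueError(f"bad SMARTS {smarts!r}")
    try:
        rdmol = to_rdkit(mol, sanitize=True)
    except Exception:
        return False
    return rdmol.HasSubstructMatch(query)
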