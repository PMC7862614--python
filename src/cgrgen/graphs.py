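"""Core graph data model: molecules, mapped reactions and condensed graphs.

A condensed graph of reaction (CGR) superimposes the reactant and product
sides of an atom-mapped reaction in one pseudomolecule.  Every atom and bond
carries a pair of states (reactant, product); elements whose two states
differ are "dynamic" and constitute the reaction center.  Atoms appearing on
one side only keep the other state as ``None`` (absent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import MappingError, ValenceError
from .valence import ORDER_VALUE, implicit_hydrogen_count, round_valence

BondKey = tuple[int, int]


def _key(i: int, j: int) -> BondKey:
    return (i, j) if i < j else (j, i)


@dataclass(frozen=True)
class AtomState:
    """State of one atom on one side of a reaction."""

    element: str
    charge: int = 0
    radical: bool = False
    aromatic: bool = False


@dataclass
class MoleculeGraph:
    """Atoms and static bonds of one molecule (or molecular fragment)."""

    atoms: list[AtomState] = field(default_factory=list)
    map_ids: list[int | None] = field(default_factory=list)
    bonds: dict[BondKey, str] = field(default_factory=dict)

    def add_atom(self, state: AtomState, map_id: int | None = None) -> int:
        self.atoms.append(state)
        self.map_ids.append(map_id)
        return len(self.atoms) - 1

    def add_bond(self, i: int, j: int, order: str) -> None:
        if i == j:
            raise ValueError("self-bond")
        self.bonds[_key(i, j)] = order

    def neighbors(self, i: int):
        for (a, b), order in self.bonds.items():
            if a == i:
                yield b, order
            elif b == i:
                yield a, order

    def explicit_valence(self, i: int) -> float:
        return sum(ORDER_VALUE[o] for _, o in self.neighbors(i))

    def connected_components(self) -> list[list[int]]:
        seen: set[int] = set()
        comps = []
        for start in range(len(self.atoms)):
            if start in seen:
                continue
            stack, comp = [start], []
            seen.add(start)
            while stack:
                i = stack.pop()
                comp.append(i)
                for j, _ in self.neighbors(i):
                    if j not in seen:
                        seen.add(j)
                        stack.append(j)
            comps.append(sorted(comp))
        return comps

    def subgraph(self, indices: list[int]) -> "MoleculeGraph":
        index = {old: new for new, old in enumerate(indices)}
        sub = MoleculeGraph(
            atoms=[self.atoms[i] for i in indices],
            map_ids=[self.map_ids[i] for i in indices],
        )
        for (a, b), order in self.bonds.items():
            if a in index and b in index:
                sub.add_bond(index[a], index[b], order)
        return sub


@dataclass(frozen=True)
class ValenceViolation:
    atom_index: int
    element: str
    observed: int
    allowed: tuple[int, ...]

    def __str__(self) -> str:
        return (
            f"atom {self.atom_index} ({self.element}): explicit valence "
            f"{self.observed} not in allowed {self.allowed}"
        )


def check_valence(mol: MoleculeGraph) -> list[ValenceViolation]:
    """All valence violations of a molecule; empty list means valid."""
    from .valence import allowed_valences

    violations = []
    for i, atom in enumerate(mol.atoms):
        allowed = allowed_valences(atom.element, atom.charge, atom.radical)
        observed = round_valence(mol.explicit_valence(i))
        h = implicit_hydrogen_count(
            atom.element, atom.charge, atom.radical, mol.explicit_valence(i)
        )
        if h is None:
            violations.append(ValenceViolation(i, atom.element, observed, allowed))
    return violations


def implicit_hydrogens(mol: MoleculeGraph) -> list[int]:
    """Per-atom implicit-hydrogen counts (raises ValenceError on violations)."""
    violations = check_valence(mol)
    if violations:
        raise ValenceError(violations)
    return [
        implicit_hydrogen_count(a.element, a.charge, a.radical, mol.explicit_valence(i))
        for i, a in enumerate(mol.atoms)
    ]


def total_hydrogens(mol: MoleculeGraph) -> int:
    """Explicit H atoms plus implicit hydrogens of a molecule."""
    implicit = implicit_hydrogens(mol)
    explicit = sum(1 for a in mol.atoms if a.element == "H")
    return explicit + sum(implicit)


@dataclass
class ReactionRecord:
    """Mapped reaction: lists of reactant/agent/product molecule graphs."""

    reactants: list[MoleculeGraph] = field(default_factory=list)
    agents: list[MoleculeGraph] = field(default_factory=list)
    products: list[MoleculeGraph] = field(default_factory=list)
    source_line: str = ""

    def reversed(self) -> "ReactionRecord":
        return ReactionRecord(
            reactants=self.products,
            agents=self.agents,
            products=self.reactants,
            source_line=self.source_line,
        )


@dataclass(frozen=True)
class CGRAtom:
    """One CGR atom: map id plus per-side states (None = absent)."""

    reactant_state: AtomState | None
    product_state: AtomState | None

    def __post_init__(self):
        if self.reactant_state is None and self.product_state is None:
            raise ValueError("CGR atom absent on both sides")

    @property
    def element(self) -> str:
        state = self.reactant_state or self.product_state
        return state.element

    @property
    def is_dynamic(self) -> bool:
        r, p = self.reactant_state, self.product_state
        if r is None or p is None:
            return False
        return r.charge != p.charge or r.radical != p.radical

    def any_state(self) -> AtomState:
        return self.reactant_state or self.product_state


class CGRGraph:
    """Condensed graph of reaction as a single two-state pseudomolecule."""

    def __init__(self):
        self.atoms: dict[int, CGRAtom] = {}
        self.bonds: dict[BondKey, tuple[str | None, str | None]] = {}

    def add_atom(self, map_id: int, atom: CGRAtom) -> None:
        if map_id in self.atoms:
            raise ValueError(f"duplicate map id {map_id}")
        self.atoms[map_id] = atom

    def add_bond(self, i: int, j: int, r_order: str | None, p_order: str | None) -> None:
        if i == j:
            raise ValueError("self-bond")
        if r_order is None and p_order is None:
            raise ValueError("bond absent on both sides")
        self.bonds[_key(i, j)] = (r_order, p_order)

    def neighbors(self, i: int):
        """Neighbors over bonds present on either side."""
        for (a, b), orders in self.bonds.items():
            if a == i:
                yield b, orders
            elif b == i:
                yield a, orders

    def dynamic_bonds(self) -> dict[BondKey, tuple[str | None, str | None]]:
        """Bonds whose two orders differ, both endpoints present on both sides.

        A bond incident to a one-sided atom merely mirrors that atom's
        absence; it is a one-sided bond, not part of the reaction center.
        """

        def both_sided(i):
            a = self.atoms[i]
            return a.reactant_state is not None and a.product_state is not None

        return {
            (i, j): v
            for (i, j), v in self.bonds.items()
            if v[0] != v[1] and both_sided(i) and both_sided(j)
        }

    def dynamic_atom_ids(self) -> list[int]:
        return [i for i, a in self.atoms.items() if a.is_dynamic]

    def is_static(self) -> bool:
        return not self.dynamic_bonds() and not self.dynamic_atom_ids()

    def connected_components(self) -> list[list[int]]:
        seen: set[int] = set()
        comps = []
        for start in self.atoms:
            if start in seen:
                continue
            stack, comp = [start], []
            seen.add(start)
            while stack:
                i = stack.pop()
                comp.append(i)
                for j, _ in self.neighbors(i):
                    if j not in seen:
                        seen.add(j)
                        stack.append(j)
            comps.append(sorted(comp))
        return comps

    def induced_subgraph(self, ids) -> "CGRGraph":
        ids = set(ids)
        sub = CGRGraph()
        for i in ids:
            sub.add_atom(i, self.atoms[i])
        for (a, b), (ro, po) in self.bonds.items():
            if a in ids and b in ids:
                sub.add_bond(a, b, ro, po)
        return sub

    def renumbered(self, mapping: dict[int, int]) -> "CGRGraph":
        """Copy with map ids replaced through `mapping` (a bijection)."""
        out = CGRGraph()
        for i, atom in self.atoms.items():
            out.add_atom(mapping[i], atom)
        for (a, b), (ro, po) in self.bonds.items():
            out.add_bond(mapping[a], mapping[b], ro, po)
        return out

    def reversed(self) -> "CGRGraph":
        """Swap reactant and product states everywhere."""
        out = CGRGraph()
        for i, atom in self.atoms.items():
            out.add_atom(i, CGRAtom(atom.product_state, atom.reactant_state))
        for (a, b), (ro, po) in self.bonds.items():
            out.add_bond(a, b, po, ro)
        return out

    def side_atoms(self, side: str) -> list[int]:
        attr = "reactant_state" if side == "r" else "product_state"
        return [i for i, a in self.atoms.items() if getattr(a, attr) is not None]


# ---------------------------------------------------------------------------
# composition / decomposition


def _union_side(mols: list[MoleculeGraph]):
    """Merge mapped molecules of one reaction side keyed by map id."""
    states: dict[int, AtomState] = {}
    bonds: dict[BondKey, str] = {}
    for mol in mols:
        local: dict[int, int] = {}
        for idx, (atom, mid) in enumerate(zip(mol.atoms, mol.map_ids)):
            if mid is None:
                continue  # unmapped spectators never enter the CGR
            if mid in states:
                raise MappingError(f"duplicate map id {mid} on one reaction side")
            states[mid] = atom
            local[idx] = mid
        for (i, j), order in mol.bonds.items():
            if i in local and j in local:
                bonds[_key(local[i], local[j])] = order
    return states, bonds


def compose_cgr(rxn: ReactionRecord) -> CGRGraph:
    """Superimpose the mapped reactant and product graphs into one CGR.

    Agents never enter the CGR.  A bond present on one side only becomes
    dynamic (order None on the other side).  Atoms present on one side only
    keep the absent state as None.
    """
    r_states, r_bonds = _union_side(rxn.reactants)
    p_states, p_bonds = _union_side(rxn.products)
    if not set(r_states) & set(p_states):
        raise MappingError("no map id shared between reactants and products")

    cgr = CGRGraph()
    for mid in sorted(set(r_states) | set(p_states)):
        cgr.add_atom(mid, CGRAtom(r_states.get(mid), p_states.get(mid)))
    for key in sorted(set(r_bonds) | set(p_bonds)):
        cgr.add_bond(*key, r_bonds.get(key), p_bonds.get(key))
    return cgr


def _side_graph(cgr: CGRGraph, side: str) -> list[MoleculeGraph]:
    attr = "reactant_state" if side == "r" else "product_state"
    pos = 0 if side == "r" else 1
    present = {i: getattr(a, attr) for i, a in cgr.atoms.items() if getattr(a, attr)}
    whole = MoleculeGraph()
    index: dict[int, int] = {}
    for mid in sorted(present):
        index[mid] = whole.add_atom(present[mid], map_id=mid)
    for (a, b), orders in cgr.bonds.items():
        order = orders[pos]
        if order is not None and a in index and b in index:
            whole.add_bond(index[a], index[b], order)
    return [whole.subgraph(comp) for comp in whole.connected_components()]


def decompose_cgr(cgr: CGRGraph) -> ReactionRecord:
    """Split a CGR back into reactant and product molecule graphs."""
    return ReactionRecord(
        reactants=_side_graph(cgr, "r"),
        products=_side_graph(cgr, "p"),
    )


# ---------------------------------------------------------------------------
# balance accounting


def hydrogen_disbalance(rxn: ReactionRecord) -> int:
    """Total product hydrogens minus total reactant hydrogens.

    Hydrogen counts include explicit H atoms and implicit hydrogens from the
    valence table; zero for a stoichiometrically balanced reaction.
    """
    return sum(total_hydrogens(m) for m in rxn.products) - sum(
        total_hydrogens(m) for m in rxn.reactants
    )


def heavy_atom_balance(rxn: ReactionRecord) -> dict[str, int]:
    """Per-element product-minus-reactant count for heavy atoms.

    Returns only elements with a non-zero delta; empty dict means balanced.
    """
    delta: dict[str, int] = {}
    for mols, sign in ((rxn.products, 1), (rxn.reactants, -1)):
        for mol in mols:
            for atom in mol.atoms:
                if atom.element == "H":
                    continue
                delta[atom.element] = delta.get(atom.element, 0) + sign
    return {el: d for el, d in delta.items() if d != 0}
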