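"""Reader/writer for the SMILES/CGR string dialect.

The dialect follows OpenSMILES for ordinary molecules and extends it with
two bracket constructs describing chemical transformations:

* dynamic bonds ``[x>y]`` in bond position, where ``x``/``y`` are the
  reactant/product bond orders drawn from ``. - = # :`` (``.`` = no bond);
* dynamic atoms: a bracket atom may carry a charge change ``[N+>0]`` or a
  radical change ``[C*>0]`` / ``[C0>*]``.

Bracket atoms never carry explicit hydrogen counts in output; implicit
hydrogens are always recomputed from the valence table (an ``H``-count found
on input is accepted and ignored).  A full grammar reference ships in
``data/dialect.md``.
"""

from __future__ import annotations

import re

from .errors import (
    EmptyReactionError,
    SmilesSyntaxError,
    ValenceError,
)
from .graphs import (
    AtomState,
    CGRAtom,
    CGRGraph,
    MoleculeGraph,
    ReactionRecord,
    check_valence,
    decompose_cgr,
)
from .tokenizer import tokenize
from .valence import AROMATIC_ELEMENTS, ORGANIC_SUBSET, SUPPORTED_ELEMENTS

BOND_CHARS = {"-", "=", "#", ":"}
DYNAMIC_BOND_RE = re.compile(r"\[([.\-=#:])>([.\-=#:])\]$")
BRACKET_ATOM_RE = re.compile(
    r"\[(?P<element>[A-Z][a-z]?|[a-z]{1,2})"
    r"(?P<hcount>H\d*)?"
    r"(?P<charge>(?:[+-]\d*|0)(?:>(?:[+-]\d*|0))?)?"
    r"(?P<radical>\*(?:>0)?|0>\*)?"
    r"(?::(?P<map>\d+))?\]$"
)

_ORGANIC_TOKENS = {
    "B": ("B", False), "C": ("C", False), "N": ("N", False), "O": ("O", False),
    "P": ("P", False), "S": ("S", False), "F": ("F", False), "Cl": ("Cl", False),
    "Br": ("Br", False), "I": ("I", False),
    "b": ("B", True), "c": ("C", True), "n": ("N", True), "o": ("O", True),
    "p": ("P", True), "s": ("S", True),
}


def _parse_charge(spec: str) -> tuple[int, int]:
    """Charge spec -> (reactant charge, product charge)."""

    def one(tok: str) -> int:
        if tok == "0":
            return 0
        sign = 1 if tok[0] == "+" else -1
        mag = int(tok[1:]) if len(tok) > 1 else 1
        return sign * mag

    if ">" in spec:
        a, b = spec.split(">")
        return one(a), one(b)
    c = one(spec)
    return c, c


class _RawAtom:
    __slots__ = ("element", "aromatic", "charge_r", "charge_p", "rad_r", "rad_p", "map_id")

    def __init__(self, element, aromatic=False, charge_r=0, charge_p=0,
                 rad_r=False, rad_p=False, map_id=None):
        self.element = element
        self.aromatic = aromatic
        self.charge_r = charge_r
        self.charge_p = charge_p
        self.rad_r = rad_r
        self.rad_p = rad_p
        self.map_id = map_id

    @property
    def dynamic(self):
        return self.charge_r != self.charge_p or self.rad_r != self.rad_p


def _parse_bracket_atom(token: str, pos: int) -> _RawAtom:
    m = BRACKET_ATOM_RE.match(token)
    if m is None:
        raise SmilesSyntaxError(f"malformed bracket atom {token!r}", pos)
    el = m.group("element")
    aromatic = el[0].islower()
    el = el.capitalize()
    if el not in SUPPORTED_ELEMENTS:
        raise SmilesSyntaxError(f"unknown element {el!r} in {token!r}", pos)
    if aromatic and el not in AROMATIC_ELEMENTS:
        raise SmilesSyntaxError(f"element {el} cannot be aromatic", pos)
    charge_r = charge_p = 0
    if m.group("charge"):
        charge_r, charge_p = _parse_charge(m.group("charge"))
    rad_r = rad_p = False
    rspec = m.group("radical")
    if rspec == "*":
        rad_r = rad_p = True
    elif rspec == "*>0":
        rad_r = True
    elif rspec == "0>*":
        rad_p = True
    map_id = int(m.group("map")) if m.group("map") else None
    return _RawAtom(el, aromatic, charge_r, charge_p, rad_r, rad_p, map_id)


class _RawGraph:
    """Intermediate parse result before molecule/CGR materialization."""

    def __init__(self):
        self.atoms: list[_RawAtom] = []
        self.bonds: dict[tuple[int, int], tuple[str | None, str | None]] = {}

    def add_bond(self, i, j, orders, pos):
        key = (i, j) if i < j else (j, i)
        if i == j or key in self.bonds:
            raise SmilesSyntaxError("duplicate or self bond", pos)
        self.bonds[key] = orders

    @property
    def has_dynamic(self):
        return any(a.dynamic for a in self.atoms) or any(
            r != p for r, p in self.bonds.values()
        )


def _parse_raw(s: str) -> _RawGraph:
    if not s:
        raise SmilesSyntaxError("empty string", 0)
    tokens = tokenize(s)
    graph = _RawGraph()
    prev: int | None = None
    pending: tuple[str | None, str | None] | None = None
    stack: list[int] = []
    rings: dict[str, tuple[int, tuple | None]] = {}
    pos = 0
    for token in tokens:
        if token == "(":
            if prev is None:
                raise SmilesSyntaxError("branch before any atom", pos)
            stack.append(prev)
        elif token == ")":
            if not stack:
                raise SmilesSyntaxError("unmatched ')'", pos)
            prev = stack.pop()
        elif token == ".":
            if pending is not None:
                raise SmilesSyntaxError("bond before '.'", pos)
            prev = None
        elif token in BOND_CHARS:
            if pending is not None:
                raise SmilesSyntaxError("two consecutive bonds", pos)
            pending = (token, token)
        elif DYNAMIC_BOND_RE.match(token):
            m = DYNAMIC_BOND_RE.match(token)
            ro = None if m.group(1) == "." else m.group(1)
            po = None if m.group(2) == "." else m.group(2)
            if ro == po:
                raise SmilesSyntaxError(f"static bond in dynamic token {token!r}", pos)
            pending = (ro, po)
        elif token.isdigit() or token.startswith("%"):
            label = token[1:] if token.startswith("%") else token
            if prev is None:
                raise SmilesSyntaxError("ring closure before any atom", pos)
            if label in rings:
                other, obond = rings.pop(label)
                bond = pending if pending is not None else obond
                if bond is None:
                    a, b = graph.atoms[other], graph.atoms[prev]
                    o = ":" if (a.aromatic and b.aromatic) else "-"
                    bond = (o, o)
                graph.add_bond(other, prev, bond, pos)
            else:
                rings[label] = (prev, pending)
            pending = None
        else:
            # atom token
            if token.startswith("["):
                atom = _parse_bracket_atom(token, pos)
            elif token in _ORGANIC_TOKENS:
                el, arom = _ORGANIC_TOKENS[token]
                atom = _RawAtom(el, arom)
            else:
                raise SmilesSyntaxError(f"unknown token {token!r}", pos)
            idx = len(graph.atoms)
            graph.atoms.append(atom)
            if prev is not None:
                bond = pending
                if bond is None:
                    a = graph.atoms[prev]
                    o = ":" if (a.aromatic and atom.aromatic) else "-"
                    bond = (o, o)
                graph.add_bond(prev, idx, bond, pos)
            elif pending is not None:
                raise SmilesSyntaxError("dangling bond", pos)
            pending = None
            prev = idx
        pos += len(token)
    if stack:
        raise SmilesSyntaxError("unclosed branch", pos)
    if rings:
        raise SmilesSyntaxError(f"unclosed ring closure {sorted(rings)}", pos)
    if pending is not None:
        raise SmilesSyntaxError("dangling bond at end of string", pos)
    return graph


def _raw_to_cgr(graph: _RawGraph) -> CGRGraph:
    used = {a.map_id for a in graph.atoms if a.map_id is not None}
    if len(used) != sum(1 for a in graph.atoms if a.map_id is not None):
        raise SmilesSyntaxError("duplicate atom map number")
    next_id = max(used, default=0) + 1
    ids = []
    for a in graph.atoms:
        if a.map_id is not None:
            ids.append(a.map_id)
        else:
            ids.append(next_id)
            next_id += 1
    cgr = CGRGraph()
    for a, mid in zip(graph.atoms, ids):
        r = AtomState(a.element, a.charge_r, a.rad_r, a.aromatic)
        p = AtomState(a.element, a.charge_p, a.rad_p, a.aromatic)
        cgr.add_atom(mid, CGRAtom(r, p))
    for (i, j), (ro, po) in graph.bonds.items():
        cgr.add_bond(ids[i], ids[j], ro, po)
    return cgr


def _validate_cgr(cgr: CGRGraph) -> None:
    rxn = decompose_cgr(cgr)
    violations = []
    for mol in rxn.reactants + rxn.products:
        violations.extend(check_valence(mol))
    if violations:
        raise ValenceError(violations)


def parse_smiles_cgr(s: str, validate: bool = True) -> CGRGraph:
    """Parse a SMILES/CGR string into a condensed graph of reaction.

    Static-only strings parse as ordinary molecules (a CGR without dynamic
    elements).  With ``validate`` (default) both derived reaction sides must
    pass the valence check, otherwise ValenceError is raised.
    """
    cgr = _raw_to_cgr(_parse_raw(s.strip()))
    if validate:
        _validate_cgr(cgr)
    return cgr


def _raw_to_molecules(graph: _RawGraph) -> list[MoleculeGraph]:
    if graph.has_dynamic:
        raise SmilesSyntaxError("dynamic tokens are not allowed in reaction fields")
    whole = MoleculeGraph()
    for a in graph.atoms:
        whole.add_atom(
            AtomState(a.element, a.charge_r, a.rad_r, a.aromatic), map_id=a.map_id
        )
    for (i, j), (ro, _) in graph.bonds.items():
        whole.add_bond(i, j, ro)
    return [whole.subgraph(c) for c in whole.connected_components()]


def parse_reaction_smiles(s: str, validate: bool = True) -> ReactionRecord:
    """Parse ``reactants>agents>products`` into a ReactionRecord.

    Whitespace around the ``>`` separators is tolerated; the middle (agents)
    field may be empty.  Atom maps are optional.
    """
    fields = s.split(">")
    if len(fields) != 3:
        raise SmilesSyntaxError("reaction SMILES needs exactly two '>' separators")
    parts = []
    for field in fields:
        field = field.strip()
        parts.append(_raw_to_molecules(_parse_raw(field)) if field else [])
    reactants, agents, products = parts
    if not reactants or not products:
        raise EmptyReactionError(f"no reactants or products in {s!r}")
    if validate:
        violations = []
        for mol in reactants + agents + products:
            violations.extend(check_valence(mol))
        if violations:
            raise ValenceError(violations)
    return ReactionRecord(reactants, agents, products, source_line=s)


# ---------------------------------------------------------------------------
# writing


def _fmt_charge(c: int) -> str:
    if c == 0:
        return "0"
    sign = "+" if c > 0 else "-"
    mag = abs(c)
    return sign + (str(mag) if mag > 1 else "")


def _atom_token(atom: CGRAtom, map_id: int | None = None) -> str:
    r, p = atom.reactant_state, atom.product_state
    el = atom.element
    aromatic = (r is None or r.aromatic) and (p is None or p.aromatic) and (
        el in AROMATIC_ELEMENTS
    )
    cr = r.charge if r else (p.charge if p else 0)
    cp = p.charge if p else (r.charge if r else 0)
    rr = r.radical if r else False
    rp = p.radical if p else False
    if cr != cp:
        charge = _fmt_charge(cr) + ">" + _fmt_charge(cp)
    elif cr != 0:
        charge = _fmt_charge(cr)
    else:
        charge = ""
    if rr and rp:
        radical = "*"
    elif rr:
        radical = "*>0"
    elif rp:
        radical = "0>*"
    else:
        radical = ""
    symbol = el.lower() if aromatic else el
    needs_bracket = (
        el not in ORGANIC_SUBSET or charge or radical or map_id is not None
    )
    if not needs_bracket:
        return symbol
    suffix = f":{map_id}" if map_id is not None else ""
    return f"[{symbol}{charge}{radical}{suffix}]"


def _bond_token(orders, a: CGRAtom, b: CGRAtom) -> str:
    ro, po = orders

    def one_sided(atom):
        return atom.reactant_state is None or atom.product_state is None

    if ro != po and one_sided(a) and one_sided(b):
        # internal bond of a one-sided fragment: written statically, the
        # fragment's departure/arrival is carried by its attachment bond
        ro = po = ro or po
    if ro == po:
        both_aromatic = all(
            (s.reactant_state is None or s.reactant_state.aromatic)
            and (s.product_state is None or s.product_state.aromatic)
            for s in (a, b)
        )
        if ro == "-" and not both_aromatic:
            return ""
        if ro == ":" and both_aromatic:
            return ""
        return ro
    return f"[{ro or '.'}>{po or '.'}]"


class _ComponentWriter:
    def __init__(self, cgr: CGRGraph, order: dict[int, int], with_maps: bool):
        self.cgr = cgr
        self.order = order  # map_id -> total-order rank (all distinct)
        self.with_maps = with_maps
        self.ring_digits: dict[tuple[int, int], str] = {}
        self.free_digits = list(range(1, 100))
        self.tree: dict[int, list[int]] = {}

    def _edge(self, i, j):
        return (i, j) if i < j else (j, i)

    def _build_tree(self, root: int) -> None:
        order = self.order
        visited = {root}

        def grow(i):
            self.tree[i] = []
            for j in sorted((j for j, _ in self.cgr.neighbors(i)), key=order.__getitem__):
                if j not in visited:
                    visited.add(j)
                    self.tree[i].append(j)
                    grow(j)

        grow(root)

    def write(self, root: int) -> str:
        self._build_tree(root)
        # back edges = graph edges not in the spanning tree
        tree_edges = {
            self._edge(i, j) for i, children in self.tree.items() for j in children
        }
        self.back_pairs = {}
        for (i, j), _ in self.cgr.bonds.items():
            if (
                i in self.tree
                and j in self.tree
                and self._edge(i, j) not in tree_edges
            ):
                self.back_pairs.setdefault(i, []).append(j)
                self.back_pairs.setdefault(j, []).append(i)
        return self._emit(root)

    def _emit(self, i: int) -> str:
        cgr = self.cgr
        mid = i if self.with_maps else None
        out = [_atom_token(cgr.atoms[i], map_id=mid)]
        for j in sorted(self.back_pairs.get(i, []), key=self.order.__getitem__):
            e = self._edge(i, j)
            if e not in self.ring_digits:
                digit = self.free_digits.pop(0)
                self.ring_digits[e] = str(digit)
                out.append(_bond_token(cgr.bonds[e], cgr.atoms[i], cgr.atoms[j]))
                out.append(str(digit) if digit < 10 else f"%{digit:02d}")
            else:
                digit = int(self.ring_digits[e])
                out.append(str(digit) if digit < 10 else f"%{digit:02d}")
                self.free_digits.insert(0, digit)
                self.free_digits.sort()
        children = self.tree[i]
        for k, j in enumerate(children):
            bond = _bond_token(cgr.bonds[self._edge(i, j)], cgr.atoms[i], cgr.atoms[j])
            inner = bond + self._emit(j)
            if k < len(children) - 1:
                out.append(f"({inner})")
            else:
                out.append(inner)
        return "".join(out)


# ---------------------------------------------------------------------------
# canonical ranking (Morgan-style refinement with tie branching)


def _bond_label(orders) -> tuple[str, str]:
    ro, po = orders
    return (ro or ".", po or ".")


def _initial_keys(cgr: CGRGraph):
    keys = {}
    for i, a in cgr.atoms.items():
        r, p = a.reactant_state, a.product_state
        profile = tuple(sorted(_bond_label(o) for _, o in cgr.neighbors(i)))
        keys[i] = (
            a.element,
            r is not None,
            p is not None,
            r.charge if r else 99,
            p.charge if p else 99,
            bool(r.radical) if r else None,
            bool(p.radical) if p else None,
            bool(r.aromatic) if r else None,
            bool(p.aromatic) if p else None,
            len(profile),
            profile,
        )
    return keys


def _dense(keys: dict) -> dict[int, int]:
    ordered = sorted(set(keys.values()), key=repr)
    rank = {k: n for n, k in enumerate(ordered)}
    return {i: rank[k] for i, k in keys.items()}


def _refine(cgr: CGRGraph, ranks: dict[int, int]) -> dict[int, int]:
    n_classes = len(set(ranks.values()))
    while True:
        keys = {
            i: (
                ranks[i],
                tuple(sorted((_bond_label(o), ranks[j]) for j, o in cgr.neighbors(i))),
            )
            for i in cgr.atoms
        }
        new = _dense(keys)
        new_classes = len(set(new.values()))
        if new_classes == n_classes:
            return new
        ranks, n_classes = new, new_classes


def _canonical_string(cgr: CGRGraph, with_maps: bool = False) -> str:
    ranks = _refine(cgr, _dense(_initial_keys(cgr)))
    budget = [5000]  # hard cap on explored leaves

    def rec(ranks: dict[int, int]) -> str:
        classes: dict[int, list[int]] = {}
        for i, r in ranks.items():
            classes.setdefault(r, []).append(i)
        tied = [r for r, members in classes.items() if len(members) > 1]
        if not tied:
            return _write_ordered(cgr, ranks, with_maps)
        target = min(tied)
        best = None
        for a in classes[target]:
            budget[0] -= 1
            if budget[0] < 0:
                break  # symmetric graphs converge anyway; keep best so far
            bumped = {i: (r, 0) if i != a else (r, -1) for i, r in ranks.items()}
            s = rec(_refine(cgr, _dense(bumped)))
            if best is None or s < best:
                best = s
        return best

    return rec(ranks)


def _write_ordered(cgr: CGRGraph, order: dict[int, int], with_maps: bool) -> str:
    fragments = []
    for comp in cgr.connected_components():
        root = min(comp, key=order.__getitem__)
        writer = _ComponentWriter(cgr, order, with_maps)
        fragments.append(writer.write(root))
    return ".".join(sorted(fragments))


def _completed(cgr: CGRGraph) -> CGRGraph:
    """Writer's view of a CGR: one-sided atoms completed to both sides.

    The string dialect cannot mark absence, so the written form presents
    every atom on both sides; internal bonds of a one-sided fragment become
    static while its attachment bonds stay dynamic.  Canonical ranking runs
    on this view so that the written string is a fixed point under
    parse/write from the first serialization.
    """
    if all(
        a.reactant_state is not None and a.product_state is not None
        for a in cgr.atoms.values()
    ):
        return cgr
    out = CGRGraph()
    one_sided = set()
    for i, a in cgr.atoms.items():
        if a.reactant_state is None or a.product_state is None:
            one_sided.add(i)
            state = a.any_state()
            out.add_atom(i, CGRAtom(state, state))
        else:
            out.add_atom(i, a)
    for (i, j), (ro, po) in cgr.bonds.items():
        if ro != po and i in one_sided and j in one_sided:
            ro = po = ro or po
        out.add_bond(i, j, ro, po)
    return out


def write_smiles_cgr(cgr: CGRGraph, canonical: bool = True, with_maps: bool = False) -> str:
    """Serialize a CGR to the SMILES/CGR dialect.

    With ``canonical`` the output is invariant under renumbering of the atom
    map ids (iterative neighborhood refinement; remaining ties broken by the
    lexicographically smallest output string).  Note that one-sided atoms
    (absent state) are written like ordinary atoms: the dialect carries no
    absence mark, so parsing the string back yields a CGR in which every atom
    is present on both sides.
    """
    if not cgr.atoms:
        return ""
    cgr = _completed(cgr)
    if canonical:
        return _canonical_string(cgr, with_maps=with_maps)
    order = {i: n for n, i in enumerate(sorted(cgr.atoms))}
    return _write_ordered(cgr, order, with_maps)


def molecule_to_cgr(mol: MoleculeGraph, start_id: int = 1) -> tuple[CGRGraph, dict[int, int]]:
    """Wrap a static molecule as a CGR (both states equal).

    Returns the CGR and the index -> map id correspondence.  Explicit map ids
    are kept; unmapped atoms receive fresh ids.
    """
    used = {m for m in mol.map_ids if m is not None}
    next_id = max(used | {start_id - 1}) + 1
    ids = {}
    for idx, mid in enumerate(mol.map_ids):
        if mid is not None:
            ids[idx] = mid
        else:
            ids[idx] = next_id
            next_id += 1
    cgr = CGRGraph()
    for idx, atom in enumerate(mol.atoms):
        cgr.add_atom(ids[idx], CGRAtom(atom, atom))
    for (i, j), o in mol.bonds.items():
        cgr.add_bond(ids[i], ids[j], o, o)
    return cgr, ids


def write_molecule(mol: MoleculeGraph, with_maps: bool = False, canonical: bool = False) -> str:
    """Serialize one molecule; ``with_maps`` writes ``[..:n]`` atom maps."""
    cgr, _ = molecule_to_cgr(mol)
    return write_smiles_cgr(cgr, canonical=canonical, with_maps=with_maps)


def write_reaction_smiles(rxn: ReactionRecord, with_maps: bool = True) -> str:
    """Serialize a ReactionRecord as ``reactants>agents>products``."""

    def side(mols):
        return ".".join(write_molecule(m, with_maps=with_maps) for m in mols)

    return f"{side(rxn.reactants)}>{side(rxn.agents)}>{side(rxn.products)}"
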