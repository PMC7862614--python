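"""Reaction centers, bounded environments and simplified reactions.

The reaction center (RC) of a CGR is the connected subgraph of its dynamic
atoms and bonds — everything the transformation touches.  RC+n extends the
center by all atoms within n bond hops and every bond among the included
atoms; RC+2 ("closest environment including second neighbors") defines the
simplified reaction, a general reactivity pattern with truncated bonds
capped by implicit hydrogens.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import ArgumentError, NoReactionCenterError
from .graphs import AtomState, CGRAtom, CGRGraph, ReactionRecord, decompose_cgr

SUZUKI_Q_ELEMENTS = frozenset({"C", "N", "O", "S", "Si"})


@dataclass(frozen=True)
class ReactionCenterMotif:
    """RC / RC+n substructural motif of one CGR."""

    level: int
    subgraph: CGRGraph
    anchor: frozenset  # map ids of the dynamic core

    @property
    def atom_ids(self) -> frozenset:
        return frozenset(self.subgraph.atoms)


@dataclass(frozen=True)
class SuzukiAssignment:
    """Generalized Suzuki coupling B-C + Q-L >> B + C-Q + L."""

    q_element: str
    l_element: str | None  # None = implicit hydrogen leaving group
    boron_id: int
    carbon_id: int
    q_id: int
    l_id: int | None


def _core_atom_ids(cgr: CGRGraph) -> set[int]:
    core = set(cgr.dynamic_atom_ids())
    for (i, j) in cgr.dynamic_bonds():
        core.add(i)
        core.add(j)
    return core


def extract_rc(cgr: CGRGraph) -> list[ReactionCenterMotif]:
    """Level-0 motifs, one per connected component of the dynamic subgraph.

    More than one motif signals a multistep transformation.  A static CGR
    yields an empty list.
    """
    core = _core_atom_ids(cgr)
    if not core:
        return []
    dynamic = cgr.dynamic_bonds()
    # connected components over dynamic bonds only
    seen: set[int] = set()
    motifs = []
    for start in sorted(core):
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        seen.add(start)
        while stack:
            i = stack.pop()
            for (a, b) in dynamic:
                if a == i or b == i:
                    j = b if a == i else a
                    if j not in seen:
                        seen.add(j)
                        comp.add(j)
                        stack.append(j)
        sub = CGRGraph()
        for i in sorted(comp):
            sub.add_atom(i, cgr.atoms[i])
        for (a, b), (ro, po) in dynamic.items():
            if a in comp and b in comp:
                sub.add_bond(a, b, ro, po)
        motifs.append(ReactionCenterMotif(0, sub, frozenset(comp)))
    return motifs


def expand_environment(cgr: CGRGraph, motif: ReactionCenterMotif, n: int) -> ReactionCenterMotif:
    """RC+n: breadth-first n-shell closure of the motif's dynamic core."""
    if n < 0:
        raise ArgumentError("environment level must be non-negative")
    for i in motif.anchor:
        if i not in cgr.atoms or cgr.atoms[i] != motif.subgraph.atoms.get(i):
            raise ArgumentError("motif does not belong to this CGR")
    if n == 0:
        return ReactionCenterMotif(0, motif.subgraph, motif.anchor)
    atoms = set(motif.anchor)
    frontier = set(atoms)
    for _ in range(n):
        nxt = set()
        for i in frontier:
            for j, _orders in cgr.neighbors(i):
                if j not in atoms:
                    nxt.add(j)
        atoms |= nxt
        frontier = nxt
        if not frontier:
            break
    return ReactionCenterMotif(n, cgr.induced_subgraph(atoms), motif.anchor)


def _aromatic_components(cgr: CGRGraph) -> list[set[int]]:
    """Connected components over static aromatic bonds."""
    adj: dict[int, set[int]] = {}
    for (i, j), (ro, po) in cgr.bonds.items():
        if ro == ":" or po == ":":
            adj.setdefault(i, set()).add(j)
            adj.setdefault(j, set()).add(i)
    comps, seen = [], set()
    for start in adj:
        if start in seen:
            continue
        comp, stack = {start}, [start]
        seen.add(start)
        while stack:
            i = stack.pop()
            for j in adj.get(i, ()):
                if j not in seen:
                    seen.add(j)
                    comp.add(j)
                    stack.append(j)
        comps.append(comp)
    return comps


def _dearomatize(atom: CGRAtom) -> CGRAtom:
    def fix(state: AtomState | None):
        return None if state is None else replace(state, aromatic=False)

    return CGRAtom(fix(atom.reactant_state), fix(atom.product_state))


def simplify_cgr(cgr: CGRGraph, environment: int = 2) -> CGRGraph:
    """Sub-CGR induced on RC+2 atoms, with aromatic-ring boundary handling.

    An aromatic system cut by the boundary is kept whole when at least half
    of its atoms fall inside; otherwise the included atoms are de-aromatized
    (their cut bonds are capped with implicit hydrogens on decomposition).
    """
    motifs = extract_rc(cgr)
    if not motifs:
        raise NoReactionCenterError("CGR has no dynamic atoms or bonds")
    keep: set[int] = set()
    for motif in motifs:
        keep |= set(expand_environment(cgr, motif, environment).atom_ids)
    dearomatize: set[int] = set()
    for comp in _aromatic_components(cgr):
        inside = comp & keep
        if not inside:
            continue
        if len(inside) >= len(comp) / 2:
            keep |= comp
        else:
            dearomatize |= inside
    sub = cgr.induced_subgraph(keep)
    if dearomatize:
        fixed = CGRGraph()
        for i, atom in sub.atoms.items():
            fixed.add_atom(i, _dearomatize(atom) if i in dearomatize else atom)
        for (i, j), (ro, po) in sub.bonds.items():
            if i in dearomatize or j in dearomatize:
                ro = "-" if ro == ":" else ro
                po = "-" if po == ":" else po
            fixed.add_bond(i, j, ro, po)
        sub = fixed
    return sub


def simplify_reaction(cgr: CGRGraph, environment: int = 2) -> ReactionRecord:
    """Simplified reaction: the general reactivity pattern around the RC."""
    return decompose_cgr(simplify_cgr(cgr, environment))


def match_suzuki(motif: ReactionCenterMotif) -> SuzukiAssignment | None:
    """Recognize the generalized Suzuki pattern in a level-0 motif.

    Requires a broken B-C single bond and a formed C-Q single bond sharing
    the same carbon, with Q in {C, N, O, S, Si}.  L is the atom Q loses a
    single bond to (implicit hydrogen when Q loses no bond).
    """
    if motif.level != 0:
        raise ArgumentError("Suzuki matching operates on level-0 motifs")
    sub = motif.subgraph
    broken, formed = [], []
    for (i, j), (ro, po) in sub.bonds.items():
        if ro == "-" and po is None:
            broken.append((i, j))
        elif ro is None and po == "-":
            formed.append((i, j))
    for (a, b) in broken:
        for (i, j) in formed:
            pair = {a: b, b: a}
            # the carbon both bonds share
            for c in (i, j):
                if c in pair and sub.atoms[c].element == "C":
                    boron = pair[c]
                    q = j if c == i else i
                    if sub.atoms[boron].element != "B":
                        continue
                    if sub.atoms[q].element not in SUZUKI_Q_ELEMENTS:
                        continue
                    l_id = None
                    for (x, y) in broken:
                        if q in (x, y) and {x, y} != {a, b}:
                            l_id = y if x == q else x
                            break
                    l_el = sub.atoms[l_id].element if l_id is not None else None
                    return SuzukiAssignment(
                        sub.atoms[q].element, l_el, boron, c, q, l_id
                    )
    return None
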