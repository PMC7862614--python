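"""Dataset standardization and the generated-reaction post-processing ledger.

Two roles:

* curating a training corpus — standardization (aromatization, functional
  group normal forms), removal of empty/invalid reactions, restriction to
  the most frequent reaction centers;
* post-processing decoded strings, in the fixed stage order
  validate -> balance -> simplify -> novelty -> chemical filters -> enthalpy,
  with every keep/discard decision recorded in a CurationReport.

Reaction feasibility is screened with an additive bond-energy enthalpy:
dH = sum E(bonds broken) - sum E(bonds formed) over the dynamic bonds only
(static bonds cancel).  Within a family of similar reactions, activation
energies trend with reaction enthalpies (the Bell-Evans-Polanyi rationale),
so an exothermic estimate is a weak feasibility argument, not a prediction.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources

from .errors import (
    BalanceFailure,
    MissingBondEnergyError,
    ValenceError,
)
from .graphs import (
    AtomState,
    CGRGraph,
    MoleculeGraph,
    ReactionRecord,
    check_valence,
    compose_cgr,
    decompose_cgr,
    heavy_atom_balance,
    hydrogen_disbalance,
    implicit_hydrogens,
)
from .novelty import reaction_signatures
from .smiles import parse_smiles_cgr, write_molecule

# ---------------------------------------------------------------------------
# curation report


@dataclass
class CurationRecord:
    index: int
    line: str
    stage: str
    status: str  # kept / discarded / annotated
    reason: str = ""


@dataclass
class CurationReport:
    records: list[CurationRecord] = field(default_factory=list)

    def log(self, index, line, stage, status, reason=""):
        self.records.append(CurationRecord(index, line, stage, status, reason))

    def tallies(self) -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {}
        for rec in self.records:
            stage = out.setdefault(rec.stage, {})
            key = rec.status if not rec.reason else f"{rec.status}({rec.reason})"
            stage[key] = stage.get(key, 0) + 1
        return out

    def discarded_indices(self) -> set[int]:
        return {r.index for r in self.records if r.status == "discarded"}

    def to_tsv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["index", "stage", "status", "reason", "line"])
            for r in self.records:
                writer.writerow([r.index, r.stage, r.status, r.reason, r.line])

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.tallies(), fh, indent=1)


# ---------------------------------------------------------------------------
# standardization


def _molecule_key(mol: MoleculeGraph) -> str:
    return write_molecule(mol, with_maps=False, canonical=True)


def standardize(rxn: ReactionRecord, normalize: bool = True):
    """Standardized reaction, or (None, reason) when discarded.

    Aromatizes every molecule, applies functional-group normal forms, and
    discards empty reactions (identical sides, or a missing side) and
    valence-invalid reactions.  Returns ``(reaction, reason)`` where
    ``reaction`` is None on discard.
    """
    from .rdkit_bridge import aromatize, normalize_groups

    if not rxn.reactants or not rxn.products:
        return None, "empty"

    def clean(mols):
        out = []
        for mol in mols:
            if check_valence(mol):
                raise ValenceError(check_valence(mol))
            out.append(normalize_groups(mol) if normalize else aromatize(mol))
        return out

    try:
        reactants = clean(rxn.reactants)
        agents = clean(rxn.agents)
        products = clean(rxn.products)
    except ValenceError:
        return None, "valence"
    except Exception:
        return None, "standardization"
    if sorted(map(_molecule_key, reactants)) == sorted(map(_molecule_key, products)):
        return None, "empty"
    return ReactionRecord(reactants, agents, products, rxn.source_line), ""


def curate_corpus(reactions, report: CurationReport | None = None):
    """Standardize a corpus; returns (kept reactions, CurationReport)."""
    report = report if report is not None else CurationReport()
    kept = []
    for idx, rxn in enumerate(reactions):
        std, reason = standardize(rxn)
        if std is None:
            report.log(idx, rxn.source_line, "standardize", "discarded", reason)
        else:
            report.log(idx, rxn.source_line, "standardize", "kept")
            kept.append(std)
    return kept, report


def filter_frequent_rcs(reactions, top_k: int):
    """Keep reactions whose every level-0 signature ranks in the top_k.

    Frequencies count reactions containing each signature; ties broken by
    signature value (deterministic).
    """
    sig_lists = []
    counts: dict[int, int] = {}
    for rxn in reactions:
        cgr = rxn if isinstance(rxn, CGRGraph) else compose_cgr(rxn)
        sigs = {s.hash for s in reaction_signatures(cgr, levels=(0,))[0]}
        sig_lists.append(sigs)
        for h in sigs:
            counts[h] = counts.get(h, 0) + 1
    ranked = sorted(counts, key=lambda h: (-counts[h], h))
    allowed = set(ranked[:top_k])
    return [
        rxn for rxn, sigs in zip(reactions, sig_lists) if sigs and sigs <= allowed
    ]


# ---------------------------------------------------------------------------
# generated-string validation


def validate_generated(strings, report: CurationReport | None = None):
    """Parse decoder output; keep syntactically and valence-valid CGRs.

    Returns ``(kept, report)`` where kept is a list of (index, CGRGraph).
    """
    report = report if report is not None else CurationReport()
    kept = []
    for idx, s in enumerate(strings):
        try:
            cgr = parse_smiles_cgr(s, validate=True)
        except ValenceError:
            report.log(idx, s, "validate", "discarded", "valence")
            continue
        except Exception:
            report.log(idx, s, "validate", "discarded", "syntax")
            continue
        report.log(idx, s, "validate", "kept")
        kept.append((idx, cgr))
    return kept, report


# ---------------------------------------------------------------------------
# water balancing


def balance_with_water(rxn: ReactionRecord) -> ReactionRecord:
    """Correct the +2-hydrogen boron pathology by adding one water molecule.

    Applies when the products carry two more hydrogens than the reactants
    with heavy atoms balanced, and a boron product atom gained a capping
    implicit hydrogen from a broken bond.  One H2O is added as a reactant
    and boron's capping hydrogen becomes a hydroxyl.  Already balanced input
    is returned unchanged; anything else raises BalanceFailure.
    """
    disbalance = hydrogen_disbalance(rxn)
    if disbalance == 0:
        return rxn
    if disbalance != 2 or heavy_atom_balance(rxn):
        raise BalanceFailure(
            f"not the +2/boron case (dH={disbalance}, heavy={heavy_atom_balance(rxn)})"
        )

    def boron_implicit(mols):
        out = {}
        for mol in mols:
            hs = implicit_hydrogens(mol)
            for i, (atom, mid) in enumerate(zip(mol.atoms, mol.map_ids)):
                if atom.element == "B":
                    out[mid if mid is not None else ("anon", id(mol), i)] = (mol, i, hs[i])
        return out

    r_boron = boron_implicit(rxn.reactants)
    p_boron = boron_implicit(rxn.products)
    target = None
    for key, (mol, i, h) in p_boron.items():
        h_before = r_boron.get(key, (None, None, 0))[2]
        if h >= 1 and h > h_before:
            target = (mol, i)
            break
    if target is None:
        raise BalanceFailure("no boron atom with a capping hydrogen in the products")

    used = {m for side in (rxn.reactants, rxn.products) for mol in side for m in mol.map_ids if m}
    new_id = max(used, default=0) + 1
    water = MoleculeGraph()
    water.add_atom(AtomState("O"), map_id=new_id)
    mol, i = target
    patched = MoleculeGraph(
        atoms=list(mol.atoms), map_ids=list(mol.map_ids), bonds=dict(mol.bonds)
    )
    j = patched.add_atom(AtomState("O"), map_id=new_id)
    patched.add_bond(i, j, "-")
    products = [patched if m is mol else m for m in rxn.products]
    out = ReactionRecord(
        reactants=list(rxn.reactants) + [water],
        agents=list(rxn.agents),
        products=products,
        source_line=rxn.source_line,
    )
    if hydrogen_disbalance(out) != 0 or heavy_atom_balance(out):
        raise BalanceFailure("water correction did not balance the reaction")
    return out


# ---------------------------------------------------------------------------
# chemical filters


def load_unstable_patterns(path=None) -> list[tuple[str, str]]:
    """(SMARTS, name) pairs from a pattern file (default: shipped list)."""
    if path is None:
        text = resources.files("cgrgen.data").joinpath("unstable_groups.smarts").read_text()
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    patterns = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        smarts, _, name = line.partition("\t")
        patterns.append((smarts, name or smarts))
    return patterns


def chemical_filters(cgr: CGRGraph, patterns=None) -> tuple[bool, list[str]]:
    """Heuristic feasibility screen; returns (passed, reason codes).

    Fails on C-C single-bond cleavage, on a leaving fragment attached
    through carbon, and on unstable-group SMARTS matches in the products.
    """
    from .rdkit_bridge import matches_smarts

    if patterns is None:
        patterns = load_unstable_patterns()
    reasons = []
    broken_pairs = []
    formed_ids: set[int] = set()
    broken_ids: set[int] = set()
    for (i, j), (ro, po) in cgr.dynamic_bonds().items():
        if ro is not None and po is None:
            broken_pairs.append((i, j, ro))
            broken_ids |= {i, j}
        if ro is None and po is not None:
            formed_ids |= {i, j}
    for i, j, ro in broken_pairs:
        if (
            ro == "-"
            and cgr.atoms[i].element == "C"
            and cgr.atoms[j].element == "C"
        ):
            reasons.append("CC_cleavage")
            break
    rxn = decompose_cgr(cgr)
    for mol in rxn.products:
        ids = {m for m in mol.map_ids if m is not None}
        if ids & formed_ids:
            continue  # fragment participates in bond formation: not leaving
        attachment = ids & broken_ids
        if attachment and any(
            mol.atoms[mol.map_ids.index(m)].element == "C" for m in attachment
        ):
            reasons.append("carbon_leaving_group")
            break
    for mol in rxn.products:
        for smarts, name in patterns:
            if matches_smarts(mol, smarts):
                reasons.append(f"unstable_group:{name}")
    return (not reasons, reasons)


# ---------------------------------------------------------------------------
# additive enthalpy


@dataclass
class BondEnergyTable:
    """Mean bond energies keyed by (element pair, order), kJ/mol."""

    energies: dict[tuple[str, str, str], float]
    source: str = ""

    @classmethod
    def load(cls, path=None) -> "BondEnergyTable":
        if path is None:
            text = resources.files("cgrgen.data").joinpath("bond_energies.tsv").read_text()
            source = "shipped mean-bond-enthalpy table"
        else:
            with open(path, encoding="utf-8") as fh:
                text = fh.read()
            source = str(path)
        energies = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            e1, e2, order, value = line.split("\t")
            key = (*sorted((e1, e2)), order)
            energies[key] = float(value)
        return cls(energies, source)

    def energy(self, e1: str, e2: str, order: str) -> float:
        key = (*sorted((e1, e2)), order)
        try:
            return self.energies[key]
        except KeyError:
            raise MissingBondEnergyError(
                f"no bond energy for {e1}-{e2} order {order!r}"
            ) from None


@dataclass
class EnthalpyEstimate:
    delta_h: float  # kJ/mol
    method: str
    bonds_broken: list
    bonds_formed: list

    @property
    def exothermic(self) -> bool:
        return self.delta_h < 0


def estimate_enthalpy(reaction, table: BondEnergyTable | None = None) -> EnthalpyEstimate:
    """Additive reaction enthalpy from the dynamic bonds of a CGR.

    dH = sum E(broken) - sum E(formed); bond-order changes contribute both
    terms.  Static bonds cancel and never enter the sum, so spectator
    decoration cannot change the estimate.
    """
    if table is None:
        table = BondEnergyTable.load()
    cgr = reaction if isinstance(reaction, CGRGraph) else compose_cgr(reaction)
    broken, formed = [], []
    delta = 0.0
    for (i, j), (ro, po) in sorted(cgr.dynamic_bonds().items()):
        e1 = cgr.atoms[i].element
        e2 = cgr.atoms[j].element
        if ro is not None:
            delta += table.energy(e1, e2, ro)
            broken.append((e1, e2, ro))
        if po is not None:
            delta -= table.energy(e1, e2, po)
            formed.append((e1, e2, po))
    return EnthalpyEstimate(delta, "additive", broken, formed)
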