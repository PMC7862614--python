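"""Seeded generator of toy atom-mapped reaction corpora with ground truth.

The corpus emulates, at desk scale, a patent-reaction extraction dominated
by cross-coupling chemistry: a configurable fraction of generalized Suzuki
couplings  Ar-B(OH)2 + Q-L >> Ar-Q + L-B(OH)2  (Q in {C, N, O, S, Si}, L a
leaving group) plus esterification and amide-coupling distractors.  Every
reaction is emitted fully mapped and valence-valid by construction, with a
manifest naming each reaction's designed reaction-center class.

Two kinds of deliberate imperfection are supported:

* ``unbalanced_fraction`` of Suzuki entries omit the boron-containing
  leaving species from the product side, reproducing the sketchy way such
  reactions are written in patent data (the +2-implicit-hydrogen pathology
  downstream);
* ``withheld_rc`` classes are never emitted, so they are genuinely novel
  with respect to any table built from the corpus.

Decorations come from a closed fragment menu (methyl, methoxy, fluoro,
nitro, phenyl) to bound string length.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass

from .errors import ConfigError
from .graphs import AtomState, CGRAtom, CGRGraph, ReactionRecord, decompose_cgr
from .smiles import write_reaction_smiles

DECORATIONS = ("", "C", "OC", "F", "NO2", "Ph")
ALKYLS = ("C", "CC", "CCC")


@dataclass
class CorpusConfig:
    n_reactions: int = 2000
    suzuki_fraction: float = 0.5
    ester_fraction: float = 0.25
    amide_fraction: float = 0.25
    q_pool: tuple = ("C",)
    l_pool: tuple = ("Br", "Cl", "I")
    decoration_depth: int = 1
    decoration_prob: float = 0.7
    withheld_rc: tuple = ()
    unbalanced_fraction: float = 0.1
    seed: int = 1

    def validate(self) -> None:
        fracs = (self.suzuki_fraction, self.ester_fraction, self.amide_fraction)
        if any(f < 0 or f > 1 for f in fracs) or sum(fracs) > 1 + 1e-9:
            raise ConfigError("class fractions must lie in [0,1] and sum to <= 1")
        if not self.q_pool or not self.l_pool:
            raise ConfigError("empty Q or L pool")
        if self.n_reactions <= 0:
            raise ConfigError("n_reactions must be positive")
        available = {
            f"suzuki:{q}-{l}" for q in self.q_pool for l in self.l_pool
        } - set(self.withheld_rc)
        if self.suzuki_fraction > 0 and not available:
            raise ConfigError("every Suzuki class is withheld")


@dataclass
class CorpusBundle:
    lines: list
    labels: list  # "Suzuki" / "other"
    manifest: list  # per-reaction dicts
    config: CorpusConfig

    def save(self, prefix) -> None:
        with open(f"{prefix}.smi", "w", encoding="utf-8") as fh:
            fh.write("\n".join(self.lines) + "\n")
        with open(f"{prefix}.labels.tsv", "w", encoding="utf-8") as fh:
            fh.write("\n".join(f"{i}\t{l}" for i, l in enumerate(self.labels)) + "\n")
        with open(f"{prefix}.manifest.json", "w", encoding="utf-8") as fh:
            json.dump({"config": asdict(self.config), "reactions": self.manifest}, fh, indent=1)


class _Builder:
    """Incremental CGR construction with fresh map ids."""

    def __init__(self):
        self.cgr = CGRGraph()
        self.next_id = 1

    def atom(self, element, aromatic=False, charge=0):
        state = AtomState(element, charge=charge, aromatic=aromatic)
        i = self.next_id
        self.cgr.add_atom(i, CGRAtom(state, state))
        self.next_id += 1
        return i

    def bond(self, i, j, order="-"):
        self.cgr.add_bond(i, j, order, order)

    def broken(self, i, j, order="-"):
        self.cgr.add_bond(i, j, order, None)

    def formed(self, i, j, order="-"):
        self.cgr.add_bond(i, j, None, order)

    def ring(self, substituent=""):
        """Benzene ring; returns the ipso atom id; para substituent optional."""
        atoms = [self.atom("C", aromatic=True) for _ in range(6)]
        for k in range(6):
            self.bond(atoms[k], atoms[(k + 1) % 6], ":")
        if substituent:
            self.decorate(atoms[3], substituent)
        return atoms[0]

    def chain(self, spec):
        """Linear carbon chain like 'CC'; returns the attachment atom id."""
        prev = None
        first = None
        for _ch in spec:
            a = self.atom("C")
            if prev is not None:
                self.bond(prev, a)
            else:
                first = a
            prev = a
        return first

    def decorate(self, anchor, name):
        if name == "C":
            self.bond(anchor, self.atom("C"))
        elif name == "OC":
            o = self.atom("O")
            self.bond(anchor, o)
            self.bond(o, self.atom("C"))
        elif name == "F":
            self.bond(anchor, self.atom("F"))
        elif name == "NO2":
            n = self.atom("N", charge=1)
            self.bond(anchor, n)
            self.cgr.add_bond(n, self.atom("O"), "=", "=")
            self.bond(n, self.atom("O", charge=-1))
        elif name == "Ph":
            self.bond(anchor, self.ring())
        elif name:
            raise ConfigError(f"unknown decoration {name!r}")


def _pick_decoration(rng, cfg: CorpusConfig) -> str:
    if cfg.decoration_depth < 1 or rng.random() > cfg.decoration_prob:
        return ""
    return rng.choice(DECORATIONS[1:])


def build_suzuki(q="C", l="Br", deco_b="", deco_e="", boron_partner="OO") -> CGRGraph:
    """Generalized Suzuki CGR: Ar-B(X)(Y) + Q-L >> Ar-Q + L-B(X)(Y).

    ``boron_partner`` gives the two heteroatoms on boron ("OO" boronic acid,
    "ON" the aminoboron variant used as a first-environment novelty probe).
    """
    b = _Builder()
    boron = b.atom("B")
    for el in boron_partner:
        b.bond(boron, b.atom(el))
    ipso = b.ring(deco_b)
    b.broken(boron, ipso)
    if q == "C":
        qa = b.ring(deco_e)
    elif q in ("N", "Si"):
        qa = b.atom(q)
        for _ in range(2 if q == "N" else 3):
            b.bond(qa, b.atom("C"))
    elif q in ("O", "S"):
        qa = b.atom(q)
        b.bond(qa, b.atom("C"))
    else:
        raise ConfigError(f"unsupported coupling partner {q!r}")
    la = b.atom(l)
    b.broken(qa, la)
    b.formed(ipso, qa)
    b.formed(boron, la)
    return b.cgr


def build_condensation(nucleophile="O", r_acid="C", r_nu="C") -> CGRGraph:
    """Esterification (O) or amide coupling (N): acid + HX-R >> product + H2O."""
    b = _Builder()
    acyl = b.atom("C")
    r = b.chain(r_acid)
    b.bond(acyl, r)
    b.cgr.add_bond(acyl, b.atom("O"), "=", "=")
    leaving_o = b.atom("O")
    b.broken(acyl, leaving_o)
    nu = b.atom(nucleophile)
    b.bond(nu, b.chain(r_nu))
    b.formed(acyl, nu)
    return b.cgr


def _suzuki_record(cgr: CGRGraph, unbalanced: bool) -> ReactionRecord:
    rxn = decompose_cgr(cgr)
    if unbalanced:
        products = [m for m in rxn.products if "B" not in {a.element for a in m.atoms}]
        rxn = ReactionRecord(rxn.reactants, rxn.agents, products)
    return rxn


def generate_corpus(cfg: CorpusConfig | None = None) -> CorpusBundle:
    """Mapped reaction lines + class labels + ground-truth manifest."""
    cfg = cfg or CorpusConfig()
    cfg.validate()
    rng = random.Random(cfg.seed)
    lines, labels, manifest = [], [], []
    for idx in range(cfg.n_reactions):
        u = rng.random()
        if u < cfg.suzuki_fraction:
            for _ in range(100):
                q = rng.choice(cfg.q_pool)
                l = rng.choice(cfg.l_pool)
                rc_class = f"suzuki:{q}-{l}"
                if rc_class not in cfg.withheld_rc:
                    break
            else:  # pragma: no cover - guarded by validate()
                raise ConfigError("could not draw a non-withheld Suzuki class")
            deco_b = _pick_decoration(rng, cfg)
            deco_e = _pick_decoration(rng, cfg) if q == "C" else ""
            unbalanced = rng.random() < cfg.unbalanced_fraction
            cgr = build_suzuki(q, l, deco_b, deco_e)
            rxn = _suzuki_record(cgr, unbalanced)
            label = "Suzuki"
            entry = {
                "class": "suzuki",
                "rc_class": rc_class + ("#unbal" if unbalanced else ""),
                "unbalanced": unbalanced,
            }
        else:
            kind = "ester" if (
                u < cfg.suzuki_fraction + cfg.ester_fraction
                or cfg.amide_fraction == 0
            ) else "amide"
            cgr = build_condensation(
                "O" if kind == "ester" else "N",
                rng.choice(ALKYLS),
                rng.choice(ALKYLS),
            )
            rxn = decompose_cgr(cgr)
            label = "other"
            entry = {"class": kind, "rc_class": kind, "unbalanced": False}
        line = write_reaction_smiles(rxn, with_maps=True)
        entry["index"] = idx
        lines.append(line)
        labels.append(label)
        manifest.append(entry)
    return CorpusBundle(lines, labels, manifest, cfg)


def make_novelty_fixtures(cfg: CorpusConfig | None = None):
    """Reference corpus plus probes with known novelty levels.

    Returns ``(reference, probes)`` where probes is a list of
    ``(reaction line, expected level)`` with levels drawn from
    {"known", "new_RC", "new_RC_plus_1"}.  The new-RC probes use the first
    withheld Suzuki class (default Q=S); the new-RC+1 probes replace one
    boronic-acid hydroxyl by an amino group, changing the first environment
    of a reaction center the reference corpus does contain.
    """
    if cfg is None:
        cfg = CorpusConfig(
            n_reactions=300, withheld_rc=("suzuki:S-Br",), unbalanced_fraction=0.0
        )
    if not cfg.withheld_rc:
        raise ConfigError("novelty fixtures need at least one withheld class")
    reference = generate_corpus(cfg)
    probes = []
    for line in reference.lines[:3]:
        probes.append((line, "known"))
    withheld = cfg.withheld_rc[0]
    q, l = withheld.split(":")[1].split("-")
    for deco in ("", "C", "F"):
        rxn = decompose_cgr(build_suzuki(q, l, deco_b=deco))
        probes.append((write_reaction_smiles(rxn), "new_RC"))
    q0, l0 = cfg.q_pool[0], cfg.l_pool[0]
    for deco in ("", "C", "F"):
        rxn = decompose_cgr(build_suzuki(q0, l0, deco_b=deco, boron_partner="ON"))
        probes.append((write_reaction_smiles(rxn), "new_RC_plus_1"))
    return reference, probes
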