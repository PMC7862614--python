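"""Reaction signatures and hash-table novelty detection.

Each RC / RC+n motif is canonicalized to its SMILES/CGR string and digested
to a stable 64-bit hash (blake2b, fixed seed-free algorithm), giving an
isomorphism-invariant reaction signature.  A signature table stores the
per-level hash sets of a reference corpus together with exemplar strings so
hash collisions are detected rather than assumed away; a generated reaction
is novel at level 0 (new RC) when its level-0 signature is absent, and novel
at level 1 (new RC+1) when the RC is known but its first environment is not.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

from .center import ReactionCenterMotif, expand_environment, extract_rc
from .errors import NoReactionCenterError
from .graphs import CGRGraph, compose_cgr
from .smiles import write_smiles_cgr

NOVELTY_LEVELS = ("known", "new_RC_plus_1", "new_RC")


@dataclass(frozen=True)
class ReactionSignature:
    level: int
    hash: int  # 64-bit unsigned
    canonical: str

    @staticmethod
    def of(motif: ReactionCenterMotif) -> "ReactionSignature":
        canonical = write_smiles_cgr(motif.subgraph, canonical=True)
        digest = hashlib.blake2b(canonical.encode(), digest_size=8).digest()
        return ReactionSignature(motif.level, int.from_bytes(digest, "big"), canonical)


def signature(motif: ReactionCenterMotif) -> ReactionSignature:
    """Isomorphism-invariant signature of a motif (stable across runs)."""
    return ReactionSignature.of(motif)


def reaction_signatures(cgr: CGRGraph, levels=(0, 1)) -> dict[int, list[ReactionSignature]]:
    """Per-level signatures of every motif of a CGR."""
    motifs = extract_rc(cgr)
    out: dict[int, list[ReactionSignature]] = {}
    for level in levels:
        sigs = []
        for motif in motifs:
            expanded = expand_environment(cgr, motif, level)
            sigs.append(signature(expanded))
        out[level] = sigs
    return out


@dataclass
class SignatureTable:
    """Per-level signature hash sets with exemplar canonical strings."""

    levels: tuple[int, ...] = (0, 1)
    entries: dict[int, dict[int, str]] = field(default_factory=dict)  # level -> hash -> exemplar
    provenance: dict = field(default_factory=dict)
    collisions: list = field(default_factory=list)

    def add(self, sig: ReactionSignature) -> None:
        table = self.entries.setdefault(sig.level, {})
        existing = table.get(sig.hash)
        if existing is None:
            table[sig.hash] = sig.canonical
        elif existing != sig.canonical:
            # genuine 64-bit collision: keep both exemplars, fall back to
            # string comparison in lookups
            self.collisions.append((sig.level, sig.hash, existing, sig.canonical))

    def __contains__(self, sig: ReactionSignature) -> bool:
        table = self.entries.get(sig.level, {})
        existing = table.get(sig.hash)
        if existing is None:
            return False
        if existing == sig.canonical:
            return True
        return any(
            lvl == sig.level and h == sig.hash and s == sig.canonical
            for lvl, h, _e, s in self.collisions
        )

    def distinct_counts(self) -> dict[int, int]:
        return {lvl: len(t) for lvl, t in self.entries.items()}

    def save(self, path) -> None:
        doc = {
            "version": 1,
            "levels": list(self.levels),
            "provenance": self.provenance,
            "entries": {
                str(lvl): {str(h): s for h, s in table.items()}
                for lvl, table in self.entries.items()
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def load(cls, path) -> "SignatureTable":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        table = cls(levels=tuple(doc["levels"]), provenance=doc.get("provenance", {}))
        table.entries = {
            int(lvl): {int(h): s for h, s in entries.items()}
            for lvl, entries in doc["entries"].items()
        }
        return table


def build_table(reactions, levels=(0, 1), provenance=None) -> SignatureTable:
    """Signature table over an iterable of ReactionRecord or CGRGraph.

    Per-reaction failures (e.g. mapping errors) are recorded in
    ``table.provenance['failures']`` rather than raised.
    """
    table = SignatureTable(levels=tuple(levels), provenance=dict(provenance or {}))
    failures = []
    n = 0
    for idx, rxn in enumerate(reactions):
        n += 1
        try:
            cgr = rxn if isinstance(rxn, CGRGraph) else compose_cgr(rxn)
            for sigs in reaction_signatures(cgr, levels).values():
                for sig in sigs:
                    table.add(sig)
        except Exception as exc:  # noqa: BLE001 - logged, never fatal
            failures.append((idx, f"{type(exc).__name__}: {exc}"))
    table.provenance.setdefault("n_reactions", n)
    if failures:
        table.provenance["failures"] = failures
    return table


@dataclass(frozen=True)
class NoveltyVerdict:
    overall: str  # max novelty over motifs
    per_motif: tuple  # (level-0 signature, verdict) per motif


def classify_novelty(cgr: CGRGraph, table: SignatureTable) -> NoveltyVerdict:
    """Classify each motif of a CGR as known / new_RC_plus_1 / new_RC.

    A multistep CGR (several motifs) is summarized by the per-motif maximum
    novelty; motif detail is preserved in the verdict.
    """
    if not {0, 1} <= set(table.levels):
        raise ValueError("table must be built with levels including {0, 1}")
    motifs = extract_rc(cgr)
    if not motifs:
        raise NoReactionCenterError("no reaction center to classify")
    detail = []
    for motif in motifs:
        sig0 = signature(motif)
        sig1 = signature(expand_environment(cgr, motif, 1))
        if sig0 not in table:
            verdict = "new_RC"
        elif sig1 not in table:
            verdict = "new_RC_plus_1"
        else:
            verdict = "known"
        detail.append((sig0, verdict))
    overall = max((v for _s, v in detail), key=NOVELTY_LEVELS.index)
    return NoveltyVerdict(overall, tuple(detail))
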