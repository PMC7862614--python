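"""End-to-end workflow: curate -> encode -> train -> map -> sample -> decode
-> post-process, with cached artifacts and a consistent report funnel.

All randomness derives from one top-level seed (per-stage offsets), so a
rerun with the same configuration reproduces identical tallies.  Every
stage writes its artifact into the output directory and is skipped when the
artifact already exists, making the pipeline resumable.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import gtm as gtm_mod
from .autoencoder import AEConfig, Seq2SeqAutoencoder, TrainConfig
from .center import extract_rc, match_suzuki, simplify_cgr
from .curation import (
    BondEnergyTable,
    CurationReport,
    balance_with_water,
    chemical_filters,
    estimate_enthalpy,
    filter_frequent_rcs,
    load_unstable_patterns,
    validate_generated,
)
from .errors import BalanceFailure, CGRGenError, ConfigError
from .graphs import compose_cgr
from .novelty import SignatureTable, build_table, classify_novelty
from .smiles import parse_reaction_smiles, write_reaction_smiles, write_smiles_cgr
from .synthetic import CorpusConfig, generate_corpus
from .tokenizer import Vocabulary, tokenize


@dataclass
class PipelineConfig:
    out_dir: str = "artifacts"
    seed: int = 1
    corpus: dict = field(default_factory=dict)  # CorpusConfig overrides
    corpus_path: str | None = None  # pre-existing reaction file instead
    top_k_rcs: int | None = None
    ae: dict = field(default_factory=dict)  # AEConfig overrides
    train: dict = field(default_factory=dict)  # TrainConfig overrides
    gtm: dict = field(default_factory=dict)  # fit() overrides
    zone_class: str = "Suzuki"
    min_purity: float = 0.9
    min_density: float = 1.0
    n_samples: int = 500
    apply_filters: bool = True

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text(encoding="utf-8")
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            doc = yaml.safe_load(text)
        else:
            doc = json.loads(text)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**doc)


def _stage_seed(cfg: PipelineConfig, offset: int) -> int:
    return (cfg.seed * 1000 + offset) % (2**31 - 1)


def postprocess_generated(
    strings,
    table: SignatureTable,
    energy_table: BondEnergyTable | None = None,
    patterns=None,
    apply_filters: bool = True,
):
    """Five-step-workflow post-processing of decoded strings.

    Stage order: validate -> balance -> simplify -> novelty -> chemical
    filters -> enthalpy.  Returns (results, CurationReport) where results is
    a list of per-reaction dicts for everything that survived validation and
    balancing.
    """
    energy_table = energy_table or BondEnergyTable.load()
    patterns = patterns if patterns is not None else load_unstable_patterns()
    report = CurationReport()
    kept, report = validate_generated(strings, report)
    results = []
    for idx, cgr in kept:
        rxn = None
        try:
            from .graphs import decompose_cgr

            rxn = balance_with_water(decompose_cgr(cgr))
        except BalanceFailure as exc:
            report.log(idx, strings[idx], "balance", "discarded", "unbalanced")
            continue
        report.log(idx, strings[idx], "balance", "kept")
        cgr = compose_cgr(rxn)
        try:
            simplified = simplify_cgr(cgr)
        except CGRGenError:
            report.log(idx, strings[idx], "simplify", "discarded", "no_rc")
            continue
        report.log(idx, strings[idx], "simplify", "kept")
        verdict = classify_novelty(cgr, table)
        report.log(idx, strings[idx], "novelty", "annotated", verdict.overall)
        passed, reasons = (True, [])
        if apply_filters:
            passed, reasons = chemical_filters(cgr, patterns)
        if not passed:
            report.log(idx, strings[idx], "filters", "discarded", ";".join(reasons))
            continue
        report.log(idx, strings[idx], "filters", "kept")
        try:
            enthalpy = estimate_enthalpy(cgr, energy_table)
            dh = enthalpy.delta_h
        except CGRGenError:
            dh = None
        report.log(idx, strings[idx], "enthalpy", "annotated",
                   "unknown" if dh is None else ("exothermic" if dh < 0 else "endothermic"))
        motifs = extract_rc(cgr)
        suzuki = any(match_suzuki(m) is not None for m in motifs)
        results.append(
            {
                "index": idx,
                "string": strings[idx],
                "balanced": write_reaction_smiles(rxn, with_maps=False),
                "simplified": write_smiles_cgr(simplified),
                "novelty": verdict.overall,
                "suzuki_pattern": suzuki,
                "delta_h_kj_mol": dh,
            }
        )
    return results, report


def run_all(cfg: PipelineConfig) -> dict:
    """Execute the whole workflow; returns the summary dictionary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed}

    # 1. corpus ----------------------------------------------------------
    corpus_file = out / "corpus.smi"
    labels_file = out / "corpus.labels.tsv"
    if cfg.corpus_path:
        lines = Path(cfg.corpus_path).read_text().splitlines()
        lines = [l.strip() for l in lines if l.strip()]
        labels = ["unknown"] * len(lines)
        lab_path = Path(cfg.corpus_path).with_suffix(".labels.tsv")
        if lab_path.exists():
            labels = [r.split("\t")[1] for r in lab_path.read_text().splitlines() if r.strip()]
    elif corpus_file.exists():
        lines = corpus_file.read_text().splitlines()
        labels = [r.split("\t")[1] for r in labels_file.read_text().splitlines() if r.strip()]
    else:
        ccfg = CorpusConfig(**{"seed": _stage_seed(cfg, 1), **cfg.corpus})
        bundle = generate_corpus(ccfg)
        bundle.save(str(out / "corpus"))
        lines, labels = bundle.lines, bundle.labels
    summary["n_corpus"] = len(lines)

    # 2. curate ----------------------------------------------------------
    curated_file = out / "curated.smi"
    from .curation import standardize

    report = CurationReport()
    curated, kept_labels = [], []
    for idx, (line, lab) in enumerate(zip(lines, labels)):
        rxn = parse_reaction_smiles(line, validate=False)
        std, reason = standardize(rxn)
        if std is None:
            report.log(idx, line, "standardize", "discarded", reason)
        else:
            report.log(idx, line, "standardize", "kept")
            curated.append(std)
            kept_labels.append(lab)
    if cfg.top_k_rcs:
        keep = filter_frequent_rcs(curated, cfg.top_k_rcs)
        keep_ids = {id(r) for r in keep}
        kept_labels = [l for r, l in zip(curated, kept_labels) if id(r) in keep_ids]
        curated = keep
    curated_file.write_text(
        "\n".join(write_reaction_smiles(r) for r in curated) + "\n"
    )
    report.to_tsv(out / "curation_report.tsv")
    summary["n_curated"] = len(curated)

    # 3. SMILES/CGR strings ---------------------------------------------
    strings_file = out / "strings.txt"
    cgrs = [compose_cgr(r) for r in curated]
    strings = [write_smiles_cgr(c) for c in cgrs]
    strings_file.write_text("\n".join(strings) + "\n")
    max_tok = max(len(tokenize(s)) for s in strings)

    # 4. autoencoder -----------------------------------------------------
    model_file = out / "ae_model.npz"
    vocab = Vocabulary.from_corpus(strings)
    if model_file.exists():
        model = Seq2SeqAutoencoder.load(model_file)
    else:
        acfg = AEConfig(**{"max_len": max_tok + 8, **cfg.ae})
        model = Seq2SeqAutoencoder(acfg, vocab, seed=_stage_seed(cfg, 2))
        tcfg = TrainConfig(**{"seed": _stage_seed(cfg, 3), **cfg.train})
        history = model.train(strings, tcfg)
        model.save(model_file)
        with open(out / "history.csv", "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=["epoch", "train_loss", "val_loss", "lr", "events"])
            w.writeheader()
            for h in history:
                w.writerow({**h, "events": ";".join(h["events"])})
    rate, _hits = model.reconstruction_rate(strings[: min(len(strings), 500)])
    summary["reconstruction_rate"] = rate

    # 5. GTM + landscape -------------------------------------------------
    gtm_file = out / "gtm.npz"
    latents = model.encode(strings)
    if gtm_file.exists():
        gmodel = gtm_mod.GTMModel.load(gtm_file)
    else:
        gmodel = gtm_mod.fit(
            latents, seed=_stage_seed(cfg, 4), **{"grid_k": 10, "rbf_m": 5, **cfg.gtm}
        )
        gmodel.save(gtm_file)
    landscape = gtm_mod.class_landscape(gmodel, latents, kept_labels)
    with open(out / "landscape.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["node", "x", "y", "density", *landscape.classes])
        for row in landscape.to_rows(gmodel):
            w.writerow(row)

    # 6. zone + sampling -------------------------------------------------
    zone = gtm_mod.select_zone(landscape, cfg.zone_class, cfg.min_purity, cfg.min_density)
    summary["zone_size"] = int(len(zone))
    samples = gtm_mod.sample_latent(gmodel, zone, cfg.n_samples, seed=_stage_seed(cfg, 5))

    # 7. decode ----------------------------------------------------------
    generated_file = out / "generated.txt"
    decoded = model.decode(samples)
    generated_file.write_text("\n".join(decoded) + "\n")
    summary["n_generated"] = len(decoded)

    # 8. post-processing -------------------------------------------------
    table = build_table(cgrs, levels=(0, 1), provenance={"source": "training corpus"})
    table.save(out / "signature_table.json")
    results, post_report = postprocess_generated(
        decoded, table, apply_filters=cfg.apply_filters
    )
    post_report.to_tsv(out / "postprocess_report.tsv")
    with open(out / "generated_reactions.tsv", "w", newline="") as fh:
        w = csv.DictWriter(
            fh,
            fieldnames=[
                "index", "string", "balanced", "simplified", "novelty",
                "suzuki_pattern", "delta_h_kj_mol",
            ],
            delimiter="\t",
        )
        w.writeheader()
        for row in results:
            w.writerow(row)
    tallies = post_report.tallies()
    summary["postprocess"] = tallies
    summary["n_valid"] = int(tallies.get("validate", {}).get("kept", 0))
    summary["n_final"] = len(results)
    summary["novelty_counts"] = {
        lvl: sum(1 for r in results if r["novelty"] == lvl)
        for lvl in ("known", "new_RC_plus_1", "new_RC")
    }
    summary["suzuki_fraction_final"] = (
        sum(1 for r in results if r["suzuki_pattern"]) / len(results) if results else 0.0
    )
    summary["n_exothermic"] = sum(
        1 for r in results if r["delta_h_kj_mol"] is not None and r["delta_h_kj_mol"] < 0
    )
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1)
    return summary
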