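"""End-to-end pipeline driver.

Runs, on a synthetic cohort with planted truth: simulate -> discover ->
filter -> quantify/normalize -> gate -> differential expression ->
survival -> target prediction -> pathway enrichment, writing every
stage's outputs and an audit log of the thresholds actually applied
into a run directory. Identical config and seeds give identical
outputs.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as kio
from .de import paired_de
from .discover import (DEFAULT_MAX_GAP, DEFAULT_MAX_PRECURSOR,
                       DEFAULT_SIGNATURE_CUTOFF, candidates_to_frame,
                       discover_candidates)
from .enrich import enrich
from .filters import FilterThresholds, apply_filter_cascade, assign_ids
from .normalize import ExpressionMatrix, expression_gates, normalize, tmm_factors
from .simulate import (SimConfig, config_from_dict, config_to_dict,
                       generate_genome, plant_target_sites, simulate_cohort,
                       simulate_reads)
from .survival import survival_scan
from .targets import (ScoringScheme, aggregate_targets, predictions_to_frame,
                      scramble_null_filter)

ALL_STAGES = ("simulate", "discover", "filter", "quantify", "de",
              "survival", "targets", "enrich")


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    stages: tuple[str, ...] = ALL_STAGES
    discover_seed: int = 101
    scramble_seed: int = 23
    n_shuffles: int = 99
    max_gap: int = DEFAULT_MAX_GAP
    max_precursor_length: int = DEFAULT_MAX_PRECURSOR
    signature_cutoff: float = DEFAULT_SIGNATURE_CUTOFF
    de_alpha: float = 0.05
    n_pathways: int = 20
    known_mirnas: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "sim": config_to_dict(self.sim),
            "thresholds": dataclasses.asdict(self.thresholds),
            "scheme": dataclasses.asdict(self.scheme),
            "stages": list(self.stages),
            "known_mirnas": dict(self.known_mirnas),
        }
        for f in ("discover_seed", "scramble_seed", "n_shuffles", "max_gap",
                  "max_precursor_length", "signature_cutoff", "de_alpha",
                  "n_pathways"):
            d[f] = getattr(self, f)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        kw = {}
        if "sim" in d:
            kw["sim"] = config_from_dict(d.pop("sim"))
        if "thresholds" in d:
            kw["thresholds"] = FilterThresholds(**d.pop("thresholds"))
        if "scheme" in d:
            kw["scheme"] = ScoringScheme(**d.pop("scheme"))
        if "stages" in d:
            kw["stages"] = tuple(d.pop("stages"))
        kw.update(d)
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _match_candidates_to_truth(retained, truth) -> dict[str, str]:
    """Knm ID -> planted hairpin ID, by locus overlap."""
    mapping = {}
    for c in retained:
        hp = truth.hairpin_loci
        ov = hp[(hp["chrom"] == c.chrom) & (hp["start"] < c.locus.end)
                & (c.locus.start < hp["end"])]
        if len(ov):
            mapping[c.knm_id] = ov.iloc[0]["id"]
    return mapping


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute the enabled stages in their fixed order; return outdir."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log = logging.getLogger("knmir.pipeline")
    log.setLevel(logging.INFO)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    try:
        _run(config, out, log)
    finally:
        log.removeHandler(handler)
        handler.close()
    return out


def _run(config: PipelineConfig, out: Path, log: logging.Logger) -> None:
    stages = config.stages
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    for i, s in enumerate(stages):
        need = ALL_STAGES.index(s)
        done = [ALL_STAGES.index(t) for t in stages[:i]]
        missing = [ALL_STAGES[k] for k in range(need) if k not in done]
        if missing:
            raise ValueError(f"stage {s!r} requires earlier stages {missing}")
    config.to_yaml(out / "config.yaml")
    log.info("stages: %s", ", ".join(stages) if stages else "(none)")
    th = config.thresholds
    log.info("thresholds: min_locus_reads=%d structure_p_max=%g evalue_max=%g "
             "gc_sd_multiplier=%g min_total_reads=%d tmm_expression_min=%g",
             th.min_locus_reads, th.structure_p_max, th.evalue_max,
             th.gc_sd_multiplier, th.min_total_reads, th.tmm_expression_min)
    if not stages:
        return

    genome, truth = generate_genome(config.sim)
    state: dict = {"genome": genome, "truth": truth}

    if "simulate" in stages:
        kio.write_fasta(out / "genome.fa", {config.sim.chrom: genome})
        truth.hairpin_loci.to_csv(out / "truth_hairpins.tsv", sep="\t", index=False)
        truth.decoy_loci.to_csv(out / "truth_decoys.tsv", sep="\t", index=False)
        kio.write_bed(out / "rrna_trna.bed", truth.decoy_loci.rename(
            columns={"kind": "name"}).assign(score="."))
        reads = simulate_reads(genome, truth, config.sim)
        kio.write_read_table(out / "reads.tsv", reads)
        counts, annotations = simulate_cohort(truth, config.sim)
        counts.to_csv(out / "truth_counts.tsv", sep="\t")
        annotations.to_csv(out / "annotations.tsv", sep="\t", index=False)
        state.update(reads=reads, counts=counts, annotations=annotations)
        log.info("simulate: %d reads, %d hairpins, %d decoys, %d pairs",
                 len(reads), len(truth.hairpin_loci), len(truth.decoy_loci),
                 config.sim.n_pairs)

    if "discover" in stages:
        cands = discover_candidates(
            state["reads"], genome, max_gap=config.max_gap,
            max_precursor_length=config.max_precursor_length,
            signature_cutoff=config.signature_cutoff,
            n_shuffles=config.n_shuffles, seed=config.discover_seed)
        candidates_to_frame(cands).to_csv(out / "candidates.tsv", sep="\t", index=False)
        state["candidates"] = cands
        log.info("discover: %d candidates (signature_cutoff=%g, n_shuffles=%d)",
                 len(cands), config.signature_cutoff, config.n_shuffles)

    if "filter" in stages:
        bed = truth.decoy_loci.rename(columns={"kind": "name"})
        retained, report = apply_filter_cascade(
            state["candidates"], bed, config.known_mirnas, th)
        retained = assign_ids(retained)
        report.to_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)
        pd.DataFrame(report.rejections, columns=["id", "step", "reason"]).to_csv(
            out / "filter_rejections.tsv", sep="\t", index=False)
        frame = candidates_to_frame(retained)
        frame.to_csv(out / "retained_candidates.tsv", sep="\t", index=False)
        kio.write_fasta(out / "retained_mature.fa",
                        {c.knm_id: c.mature_seq for c in retained})
        state["retained"] = retained
        log.info("filter: %s", " -> ".join(f"{s}:{o}" for s, _, o in report.per_step))

    if "quantify" in stages:
        retained = state["retained"]
        mapping = _match_candidates_to_truth(retained, truth)
        rows = {}
        for c in retained:
            hp = mapping.get(c.knm_id)
            rows[c.knm_id] = (state["counts"].loc[hp].values if hp is not None
                              else np.zeros(state["counts"].shape[1], dtype=np.int64))
        counts = pd.DataFrame(rows, index=state["counts"].columns).T
        counts.index.name = "locus"
        # TMM factors and library sizes are anchored on the full
        # quantification (novel loci plus the annotated small-RNA
        # complement), as normalization assumes mostly-null features
        full_raw = ExpressionMatrix(state["counts"], "raw_counts")
        factors = tmm_factors(full_raw)
        norm_full = normalize(full_raw, factors)
        raw = ExpressionMatrix(counts, "raw_counts")
        expressed = expression_gates(raw, "sum_reads", min_sum_reads=th.min_total_reads)
        norm_cand = pd.DataFrame(
            {c: (norm_full.values.loc[mapping[c]].values if c in mapping
                 else np.zeros(norm_full.values.shape[1]))
             for c in expressed}, index=norm_full.values.columns).T
        norm_cand.index.name = "locus"
        norm = ExpressionMatrix(norm_cand, "tmm_normalized")
        gated = expression_gates(norm, "fraction_of_samples",
                                 tmm_min=th.tmm_expression_min)
        norm = ExpressionMatrix(norm.values.loc[gated], "tmm_normalized")
        counts.to_csv(out / "counts.tsv", sep="\t")
        factors.factors.to_csv(out / "tmm_factors.tsv", sep="\t")
        norm.values.to_csv(out / "normalized.tsv", sep="\t")
        state.update(norm=norm, mapping=mapping)
        log.info("quantify: %d loci counted, %d pass sum_reads>=%d, "
                 "%d pass TMM>%g in 10%% of samples",
                 len(counts), len(expressed), th.min_total_reads, len(gated),
                 th.tmm_expression_min)

    if "de" in stages:
        ann = state["annotations"]
        de_res = paired_de(state["norm"].values, ann[["sample", "pair", "condition"]])
        de_res.to_csv(out / "de.tsv", sep="\t", index=False)
        sig = de_res[de_res["bh_p"] < config.de_alpha]
        state["de"] = de_res
        state["de_sig"] = list(sig["locus"])
        log.info("de: %d/%d significant at BH-p<%g (%d up, %d down)",
                 len(sig), len(de_res), config.de_alpha,
                 int((sig["direction"] == "up").sum()),
                 int((sig["direction"] == "down").sum()))

    if "survival" in stages:
        surv = survival_scan(state["norm"].values, state["annotations"])
        surv.to_csv(out / "survival.tsv", sep="\t", index=False)
        state["survival"] = surv
        log.info("survival: %d loci tested (Gehan-Breslow-Wilcoxon, high vs low tertile)",
                 len(surv))

    if "targets" in stages:
        retained = {c.knm_id: c for c in state["retained"]}
        mirnas = {mid: retained[mid].mature_seq for mid in state["de_sig"]
                  if mid in retained}
        utrs, target_truth = plant_target_sites(mirnas, config.sim)
        kio.write_fasta(out / "utrs.fa", utrs)
        pd.DataFrame(target_truth, columns=["mirna", "gene"]).to_csv(
            out / "target_truth.tsv", sep="\t", index=False)
        per_mirna = {}
        rng = np.random.default_rng(config.scramble_seed)
        for mid, seq in mirnas.items():
            per_mirna[mid] = scramble_null_filter(
                mid, seq, utrs, seed=int(rng.integers(2 ** 31)),
                scheme=config.scheme)
        preds = [p for ps in per_mirna.values() for p in ps]
        predictions_to_frame(preds).to_csv(out / "targets.tsv", sep="\t", index=False)
        genes = aggregate_targets(per_mirna) if per_mirna else []
        pd.Series(genes, name="gene").to_csv(out / "aggregated_genes.tsv",
                                             sep="\t", index=False)
        state.update(per_mirna=per_mirna, aggregated=genes, utrs=utrs,
                     target_truth=target_truth)
        log.info("targets: %d predictions over %d miRNAs; %d genes targeted "
                 "by >=10%% of miRNAs (score>=%g, energy<=%g, 5 scrambles)",
                 len(preds), len(mirnas), len(genes), 140.0, -20.0)

    if "enrich" in stages:
        utr_genes = sorted(state["utrs"])
        rng = np.random.default_rng(np.random.SeedSequence((config.sim.seed, 4)))
        planted_genes = sorted({g for _, g in state["target_truth"]})
        pathways = {"PLANTED_TARGETS": set(planted_genes) | set(
            rng.choice(utr_genes, size=min(10, len(utr_genes)), replace=False))}
        for i in range(config.n_pathways - 1):
            size = int(rng.integers(10, 40))
            pathways[f"RANDOM_{i + 1:02d}"] = set(
                rng.choice(utr_genes, size=size, replace=False))
        query = set(state["aggregated"]) & set(utr_genes)
        if query:
            res = enrich(query, pathways, universe=set(utr_genes))
            res.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            top = res.iloc[0]
            log.info("enrich: top pathway %s (bh_p=%.3g, overlap %d)",
                     top["pathway"], top["bh_p"], top["n_overlap"])
        else:
            log.info("enrich: no aggregated target genes; nothing to test")
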