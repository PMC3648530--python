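"""Pipeline orchestration: simulate -> trim -> ingest -> outliers -> qc -> snps.

Stages communicate only via files so every intermediate is inspectable.  A
run produces a manifest listing each output with its SHA-256 checksum; with
a fixed seed and config, reruns reproduce identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Any

import pandas as pd
import yaml

from . import align_ingest, divergence, qc_stats, read_trim, snp_filter, synthetic_data

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

STAGE_ORDER = ("simulate", "trim", "ingest", "outliers", "qc", "snps")


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGE_ORDER}
    )
    inputs: dict[str, str] = field(default_factory=dict)  # fastq, blast, contigs, pileup
    simulate_params: dict[str, Any] = field(default_factory=dict)
    trim_params: dict[str, Any] = field(default_factory=dict)
    cutoffs: tuple[float | None, ...] = (1e-50, 1e-25, None)
    outlier_params: dict[str, Any] = field(default_factory=dict)
    snp_params: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in raw.items() if k in known})
        if isinstance(cfg.cutoffs, list):
            cfg.cutoffs = tuple(
                None if c in (None, "none") else float(c) for c in cfg.cutoffs
            )
        for stage in cfg.stages:
            if stage not in STAGE_ORDER:
                raise ValueError(f"unknown stage {stage!r}")
        return cfg


def load_config(path: str) -> PipelineConfig:
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    return PipelineConfig.from_dict(raw)


def _sha256(path: str) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _preflight(cfg: PipelineConfig) -> None:
    on = {s for s in STAGE_ORDER if cfg.stages.get(s)}
    sim = "simulate" in on

    def need(stage: str, key: str) -> None:
        if stage in on and not sim and key not in cfg.inputs:
            raise ValueError(
                f"stage {stage!r} enabled but no input {key!r} configured "
                "and simulation is off"
            )

    need("trim", "fastq")
    need("ingest", "blast")
    need("ingest", "contigs")
    need("snps", "pileup")
    if "outliers" in on and not sim and "blast" not in cfg.inputs and "ingest" not in on:
        raise ValueError("stage 'outliers' enabled but no alignment input available")
    for key, path in cfg.inputs.items():
        if not os.path.exists(path):
            raise ValueError(f"configured input {key}={path!r} does not exist")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the enabled stages in dependency order; return the manifest."""
    _preflight(cfg)
    os.makedirs(cfg.outdir, exist_ok=True)
    out = lambda name: os.path.join(cfg.outdir, name)  # noqa: E731
    outputs: list[str] = []
    stages_run: list[str] = []
    artefacts: dict[str, str] = dict(cfg.inputs)

    if cfg.stages.get("simulate"):
        params = synthetic_data.SimParams(seed=cfg.seed, **cfg.simulate_params)
        fasta, meta, truth = synthetic_data.simulate_contigs(params)
        synthetic_data.write_fasta(fasta, out("contigs.fasta"))
        meta.to_csv(out("contig_meta.tsv"), sep="\t", index=False)
        truth.contigs.to_csv(out("truth_contigs.tsv"), sep="\t", index=False)
        table = synthetic_data.simulate_alignment_table(params, truth)
        synthetic_data.write_blast_tab(table, out("alignments.tsv"))
        fastq, read_truth = synthetic_data.simulate_reads(params)
        with open(out("reads.fastq"), "w") as fh:
            fh.write(fastq)
        read_truth.to_csv(out("truth_reads.tsv"), sep="\t", index=False)
        contig_seqs = _fasta_to_dict(out("contigs.fasta"))
        pileup, var_truth = synthetic_data.simulate_pileup(params, contig_seqs)
        with open(out("pileup.txt"), "w") as fh:
            fh.write(pileup)
        var_truth.to_csv(out("truth_variants.tsv"), sep="\t", index=False)
        artefacts.setdefault("fastq", out("reads.fastq"))
        artefacts.setdefault("blast", out("alignments.tsv"))
        artefacts.setdefault("contigs", out("contigs.fasta"))
        artefacts.setdefault("pileup", out("pileup.txt"))
        outputs += [
            out(n)
            for n in (
                "contigs.fasta",
                "contig_meta.tsv",
                "truth_contigs.tsv",
                "alignments.tsv",
                "reads.fastq",
                "truth_reads.tsv",
                "pileup.txt",
                "truth_variants.tsv",
            )
        ]
        stages_run.append("simulate")

    if cfg.stages.get("trim"):
        spec = read_trim.TrimSpec(**cfg.trim_params)
        read_trim.trim_fastq(
            artefacts["fastq"], out("trimmed.fastq"), out("trim_log.tsv"), spec
        )
        outputs += [out("trimmed.fastq"), out("trim_log.tsv")]
        stages_run.append("trim")

    tophits: pd.DataFrame | None = None
    meta_table: pd.DataFrame | None = None
    if cfg.stages.get("ingest"):
        table = align_ingest.parse_blast_tab(artefacts["blast"])
        tophits = align_ingest.evalue_stepdown(table, cfg.cutoffs)
        tophits.to_csv(out("top_hits.tsv"), sep="\t", index=False)
        summary = align_ingest.per_chromosome_summary(tophits)
        summary.to_csv(out("chrom_summary.tsv"), sep="\t", index=False)
        unique = align_ingest.classify_unique_chromosome(table)
        unique.rename("unique_chromosome").to_frame().reset_index().to_csv(
            out("unique_chromosome.tsv"), sep="\t", index=False
        )
        meta_table = align_ingest.load_contigs(artefacts["contigs"])
        meta_table.to_csv(out("ingest_contig_meta.tsv"), sep="\t", index=False)
        outputs += [
            out("top_hits.tsv"),
            out("chrom_summary.tsv"),
            out("unique_chromosome.tsv"),
            out("ingest_contig_meta.tsv"),
        ]
        stages_run.append("ingest")

    report = None
    scores = None
    if cfg.stages.get("outliers"):
        if tophits is None:
            table = align_ingest.parse_blast_tab(artefacts["blast"])
            tophits = align_ingest.evalue_stepdown(table, cfg.cutoffs)
        scores = divergence.score_table(tophits)
        scores.to_csv(out("scores.tsv"), sep="\t", index=False)
        params = divergence.OutlierParams(**cfg.outlier_params)
        report = divergence.call_outliers(scores, params)
        with open(out("outlier_report.json"), "w") as fh:
            json.dump(
                {
                    "lower_bound": report.lower_bound,
                    "upper_bound": report.upper_bound,
                    "conserved": sorted(report.conserved),
                    "diverged": sorted(report.diverged),
                    "n_total": report.n_total,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
        outputs += [out("scores.tsv"), out("outlier_report.json")]
        stages_run.append("outliers")

    calls: list[snp_filter.SnpCall] = []
    if cfg.stages.get("snps"):
        sparams = snp_filter.SnpFilterParams(**cfg.snp_params)
        with open(artefacts["pileup"]) as fh:
            calls = snp_filter.call_snps(fh, sparams)
        snp_filter.write_snp_table(calls, out("snps.tsv"))
        snp_filter.write_vcf(calls, out("snps.vcf"))
        outputs += [out("snps.tsv"), out("snps.vcf")]
        stages_run.append("snps")

    if cfg.stages.get("qc"):
        if tophits is None or meta_table is None:
            raise ValueError("qc stage requires the ingest stage")
        merged = tophits.merge(
            meta_table, left_on="qseqid", right_on="contig_id", how="inner"
        ).rename(
            columns={"length_y": "contig_size", "length_x": "alignment_length"}
        )
        corr = qc_stats.pairwise_correlations(merged)
        corr.to_csv(out("qc_correlations.tsv"), sep="\t", index=False)
        outputs.append(out("qc_correlations.tsv"))
        if report is not None and scores is not None:
            sizes = dict(zip(meta_table["contig_id"], meta_table["length"]))
            universe = set(scores["contig_id"])
            sizes = {cid: sizes[cid] for cid in universe if cid in sizes}
            if set(sizes) == universe:
                overlap = qc_stats.size_outlier_overlap(
                    sizes,
                    report,
                    frozenset(universe),
                    divergence.OutlierParams(**cfg.outlier_params),
                )
                with open(out("qc_size_overlap.json"), "w") as fh:
                    json.dump(
                        {
                            "n_size_outliers": overlap["n_size_outliers"],
                            "n_divergence_outliers": overlap["n_divergence_outliers"],
                            "n_overlap": overlap["n_overlap"],
                            "overlap": sorted(overlap["overlap"]),
                        },
                        fh,
                        indent=2,
                        sort_keys=True,
                    )
                outputs.append(out("qc_size_overlap.json"))
        if report is not None and calls:
            sizes = dict(zip(meta_table["contig_id"], meta_table["length"]))
            per_class = {}
            for label, members in (
                ("conserved", report.conserved),
                ("diverged", report.diverged),
            ):
                snps = sum(1 for c in calls if c.contig_id in members)
                bp = sum(sizes.get(cid, 0) for cid in members)
                per_class[label] = (snps, bp)
            if per_class["conserved"][1] > 0 and per_class["diverged"][1] > 0:
                enr = qc_stats.snp_enrichment_chisq(
                    per_class["conserved"], per_class["diverged"]
                )
                with open(out("qc_enrichment.json"), "w") as fh:
                    json.dump(dataclasses.asdict(enr), fh, indent=2, sort_keys=True)
                outputs.append(out("qc_enrichment.json"))
        stages_run.append("qc")

    manifest = {
        "seed": cfg.seed,
        "stages_run": stages_run,
        "outputs": {os.path.relpath(p, cfg.outdir): _sha256(p) for p in outputs},
    }
    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _fasta_to_dict(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
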