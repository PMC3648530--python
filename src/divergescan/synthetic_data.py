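"""Synthetic inputs with known ground truth for every pipeline stage.

Generates contig FASTA, BLAST-tabular alignment tables, FASTQ reads, and
text pileups, each paired with a truth table.  All randomness derives from a
single integer seed; identical parameters reproduce byte-identical outputs.

Planted signal:

* *diverged* contigs receive a single short (19-30 bp) 100%-identity
  alignment record regardless of contig size;
* *conserved* contigs receive one near-full-length (>=95% of the contig)
  high-identity (>=95%) record;
* *background* contigs get alignment lengths proportional to contig size
  (moderate positive size/length correlation) with identities drawn from a
  clipped normal, which makes the composite score distribution right-skewed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .align_ingest import BLAST6_COLUMNS

__all__ = [
    "SimParams",
    "TruthTable",
    "simulate_contigs",
    "simulate_alignment_table",
    "simulate_reads",
    "simulate_pileup",
    "write_fasta",
    "write_blast_tab",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# fixed stream tags so each stage has an independent deterministic substream
_STREAM_CONTIGS = 1
_STREAM_ALIGN = 2
_STREAM_READS = 3
_STREAM_PILEUP = 4


@dataclass(frozen=True)
class SimParams:
    seed: int = 0
    n_contigs: int = 20_000
    contig_length_range: tuple[int, int] = (500, 3_000)
    gc_mean: float = 0.42
    identity_distribution: tuple[float, float] = (74.0, 5.0)  # mean %, sd
    n_planted_conserved: int = 4
    n_planted_diverged: int = 4
    read_count: int = 2_000
    read_length: int = 100
    quality_profile: tuple[float, float] = (35.0, -0.1)  # mean Q at cycle 1, slope
    adapter_sequences: tuple[str, ...] = ("AGATCGGAAGAGC",)
    adapter_fraction: float = 0.2
    low_quality_tail_fraction: float = 0.1
    pileup_depth_range: tuple[int, int] = (10, 60)
    variant_fraction: float = 0.01
    pileup_n_contigs: int = 5
    pileup_span: int = 2_000
    pileup_read_length: int = 50
    recoverable_depth_range: tuple[int, int] = (10, 60)

    def __post_init__(self) -> None:
        if self.n_contigs < 0 or self.read_count < 0:
            raise ValueError("counts must be non-negative")
        if self.n_planted_conserved < 0 or self.n_planted_diverged < 0:
            raise ValueError("planted counts must be non-negative")
        lo, hi = self.contig_length_range
        if lo <= 0 or hi < lo:
            raise ValueError(f"invalid contig_length_range {self.contig_length_range}")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        for frac in (self.gc_mean, self.adapter_fraction,
                     self.low_quality_tail_fraction, self.variant_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fractions must lie in [0, 1], got {frac}")
        dlo, dhi = self.pileup_depth_range
        if dlo <= 0 or dhi < dlo:
            raise ValueError(f"invalid pileup_depth_range {self.pileup_depth_range}")
        if self.n_planted_conserved + self.n_planted_diverged > self.n_contigs:
            raise ValueError("more planted contigs than contigs")
        for adapter in self.adapter_sequences:
            if len(adapter) > self.read_length:
                raise ValueError(f"adapter longer than read: {adapter!r}")
            if set(adapter.upper()) - set("ACGT"):
                raise ValueError(f"adapter must be ACGT only: {adapter!r}")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class TruthTable:
    """Ground truth: per-contig classes plus optional read/variant truth."""

    contigs: pd.DataFrame  # contig_id, planted_class, length, gc
    reads: pd.DataFrame | None = None  # read_id, adapter_*, tail_*
    variants: pd.DataFrame | None = None  # contig_id, pos, ref, alt, ...


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    # cumulative thresholds over A, C, G, T with P(C)=P(G)=gc/2
    at = (1.0 - gc) / 2.0
    cum = np.array([at, at + gc / 2.0, at + gc, 1.0])
    idx = np.searchsorted(cum, rng.random(length), side="right")
    return _BASES[idx].tobytes().decode("ascii")


def simulate_contigs(params: SimParams) -> tuple[str, pd.DataFrame, TruthTable]:
    """Generate contig FASTA text, a ContigMeta table, and the truth table.

    Conserved contigs take the maximum length of the range (they model long,
    well-aligned genomic tracks); diverged contigs take lengths in the
    208-1782 bp band (clipped to the range); background lengths are uniform.
    """
    rng = params.rng(_STREAM_CONTIGS)
    n = params.n_contigs
    lo, hi = params.contig_length_range
    classes = np.array(["background"] * n, dtype=object)
    order = rng.permutation(n)
    conserved_idx = order[: params.n_planted_conserved]
    diverged_idx = order[
        params.n_planted_conserved : params.n_planted_conserved + params.n_planted_diverged
    ]
    classes[conserved_idx] = "conserved"
    classes[diverged_idx] = "diverged"

    lengths = rng.integers(lo, hi + 1, size=n)
    lengths[conserved_idx] = hi
    div_lo, div_hi = max(208, lo), min(1782, hi)
    lengths[diverged_idx] = rng.integers(div_lo, div_hi + 1, size=len(diverged_idx))

    ids = [f"contig{i + 1:06d}" for i in range(n)]
    out = io.StringIO()
    gcs = np.empty(n)
    for i in range(n):
        seq = _random_sequence(rng, int(lengths[i]), params.gc_mean)
        gcs[i] = (seq.count("G") + seq.count("C")) / len(seq) if seq else 0.0
        out.write(f">{ids[i]}\n")
        for j in range(0, len(seq), 80):
            out.write(seq[j : j + 80] + "\n")
    meta = pd.DataFrame({"contig_id": ids, "length": lengths.astype(int), "gc": gcs})
    truth = TruthTable(
        contigs=pd.DataFrame(
            {
                "contig_id": ids,
                "planted_class": classes,
                "length": lengths.astype(int),
                "gc": gcs,
            }
        )
    )
    return out.getvalue(), meta, truth


_CHROMS = [f"chr{i}" for i in range(1, 29)] + ["chrZ"]

# background hit geometry: alignment length is a uniform fraction of contig
# size (floored), identity a clipped normal -- keeps scores strictly between
# the planted conserved and diverged signatures
_BG_FRAC = (0.05, 0.55)
_BG_IDENT_CLIP = (62.0, 92.0)
_MIN_BG_LEN = 40


def _evalue(bitscore: float) -> float:
    exponent = bitscore / 3.0
    return 0.0 if exponent > 180 else 10.0 ** (-exponent)


def simulate_alignment_table(params: SimParams, truth: TruthTable) -> pd.DataFrame:
    """Emit a BLAST outfmt-6 hit table honouring the planted classes.

    Every contig receives at least one hit; background contigs may carry
    extra, strictly weaker hits so that top-hit selection is exercised.
    """
    contigs = truth.contigs
    if len(contigs) != params.n_contigs:
        raise ValueError(
            f"truth table has {len(contigs)} contigs, params expect {params.n_contigs}"
        )
    counts = contigs["planted_class"].value_counts()
    if counts.get("conserved", 0) != params.n_planted_conserved or counts.get(
        "diverged", 0
    ) != params.n_planted_diverged:
        raise ValueError("planted class counts disagree between truth and params")

    rng = params.rng(_STREAM_ALIGN)
    ident_mean, ident_sd = params.identity_distribution
    rows: list[tuple] = []
    for contig_id, cls, size in zip(
        contigs["contig_id"], contigs["planted_class"], contigs["length"]
    ):
        size = int(size)
        if cls == "diverged":
            length = int(rng.integers(19, 31))
            pident = 100.0
            n_extra = 0
        elif cls == "conserved":
            length = int(round(size * rng.uniform(0.97, 1.0)))
            pident = round(rng.uniform(95.0, 96.0), 2)
            n_extra = 0
        else:
            frac = rng.uniform(*_BG_FRAC)
            length = max(_MIN_BG_LEN, int(round(size * frac)))
            length = min(length, size)
            pident = round(
                float(np.clip(rng.normal(ident_mean, ident_sd), *_BG_IDENT_CLIP)), 2
            )
            n_extra = int(rng.integers(0, 3))

        chrom = _CHROMS[rng.integers(0, len(_CHROMS))]
        rows.append(_make_hit(rng, contig_id, chrom, pident, length, size))
        for _ in range(n_extra):
            elen = max(20, int(round(length * rng.uniform(0.3, 0.8))))
            epid = round(max(55.0, pident - rng.uniform(1.0, 6.0)), 2)
            echrom = _CHROMS[rng.integers(0, len(_CHROMS))]
            rows.append(_make_hit(rng, contig_id, echrom, epid, elen, size))
    return pd.DataFrame(rows, columns=list(BLAST6_COLUMNS))


def _make_hit(
    rng: np.random.Generator,
    contig_id: str,
    chrom: str,
    pident: float,
    length: int,
    size: int,
) -> tuple:
    qstart = int(rng.integers(1, max(2, size - length + 2)))
    qend = qstart + length - 1
    sstart = int(rng.integers(1, 50_000_000))
    send = sstart + length - 1
    if rng.random() < 0.3:  # minus strand
        sstart, send = send, sstart
    bitscore = round(2.0 * length * pident / 100.0, 1)
    mismatch = int(round(length * (1.0 - pident / 100.0) * 0.8))
    gapopen = int(rng.integers(0, 3)) if pident < 100.0 else 0
    return (
        contig_id,
        chrom,
        pident,
        length,
        mismatch,
        gapopen,
        qstart,
        qend,
        sstart,
        send,
        _evalue(bitscore),
        bitscore,
    )


def simulate_reads(params: SimParams) -> tuple[str, pd.DataFrame]:
    """FASTQ text with per-cycle quality decay, embedded adapters, and
    planted low-quality tails, plus the per-read truth table."""
    rng = params.rng(_STREAM_READS)
    q0, slope = params.quality_profile
    L = params.read_length
    cycle_means = q0 + slope * np.arange(L)
    out = io.StringIO()
    truth_rows: list[tuple] = []
    for i in range(params.read_count):
        read_id = f"read{i + 1:07d}"
        bases = list(_random_sequence(rng, L, params.gc_mean))
        quals = np.clip(
            np.rint(rng.normal(cycle_means, 3.0)), 2, 40
        ).astype(int)

        adapter_start = adapter_end = -1
        if params.adapter_sequences and rng.random() < params.adapter_fraction:
            adapter = params.adapter_sequences[
                int(rng.integers(0, len(params.adapter_sequences)))
            ]
            adapter_start = int(rng.integers(L // 3, L - len(adapter) + 1))
            adapter_end = adapter_start + len(adapter)
            bases[adapter_start:adapter_end] = list(adapter)

        tail_start = tail_end = -1
        if rng.random() < params.low_quality_tail_fraction:
            tail_start = int(rng.integers(int(0.6 * L), L))
            tail_end = L
            quals[tail_start:] = rng.integers(2, 6, size=L - tail_start)

        qstr = "".join(chr(int(q) + 33) for q in quals)
        out.write(f"@{read_id}\n{''.join(bases)}\n+\n{qstr}\n")
        truth_rows.append((read_id, adapter_start, adapter_end, tail_start, tail_end))
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "adapter_start", "adapter_end", "tail_start", "tail_end"],
    )
    return out.getvalue(), truth


_ALT = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}


def simulate_pileup(
    params: SimParams, contigs: dict[str, str]
) -> tuple[str, pd.DataFrame]:
    """Text pileup over the first ``pileup_n_contigs`` contigs with planted
    biallelic variants, plus the variant truth table.

    Reads of fixed length tile each contig to hit a per-contig mean depth
    inside ``pileup_depth_range``; planted variant columns carry an
    alternative-allele fraction in [0.45, 0.55]; other columns contain only
    quality-implied sequencing errors.  Planted columns whose raw depth
    falls outside ``recoverable_depth_range`` are marked unrecoverable.
    """
    if not contigs:
        raise ValueError("no contigs supplied")
    rng = params.rng(_STREAM_PILEUP)
    dlo, dhi = params.pileup_depth_range
    rlo, rhi = params.recoverable_depth_range
    Lr = params.pileup_read_length
    out = io.StringIO()
    truth_rows: list[tuple] = []

    for contig_id in list(contigs)[: params.pileup_n_contigs]:
        seq = contigs[contig_id].upper()
        span = min(len(seq), params.pileup_span)
        if span < 1:
            continue
        mean_depth = rng.uniform(dlo + (dhi - dlo) * 0.25, dhi - (dhi - dlo) * 0.25)
        n_reads = max(1, int(round(mean_depth * span / Lr)))
        starts = np.sort(rng.integers(1 - Lr, span, size=n_reads))
        reads = []
        for s in starts:
            a, b = max(0, int(s)), min(span, int(s) + Lr)  # 0-based half-open
            if b <= a:
                continue
            quals = np.clip(
                np.rint(rng.normal(35.0, 2.0, size=b - a)), 12, 40
            ).astype(int)
            reads.append({"start": a, "end": b, "quals": quals, "alts": {}})

        # plant variants
        variant_positions: dict[int, str] = {}
        for pos0 in range(span):
            if seq[pos0] not in "ACGT":
                continue
            if rng.random() < params.variant_fraction:
                alt = _ALT[seq[pos0]][int(rng.integers(0, 3))]
                variant_positions[pos0] = alt

        coverage: dict[int, list[int]] = {p: [] for p in range(span)}
        for ri, rd in enumerate(reads):
            for p in range(rd["start"], rd["end"]):
                coverage[p].append(ri)

        for pos0, alt in variant_positions.items():
            cov = coverage[pos0]
            depth = len(cov)
            k_alt = 0
            if depth:
                k_alt = int(round(depth * rng.uniform(0.45, 0.55)))
                k_alt = max(k_alt, int(np.ceil(0.45 * depth)))
                chosen = rng.permutation(len(cov))[:k_alt]
                for ci in chosen:
                    reads[cov[ci]]["alts"][pos0] = alt
            recoverable = bool(depth and rlo <= depth <= rhi)
            truth_rows.append(
                (contig_id, pos0 + 1, seq[pos0], alt, depth, k_alt, recoverable)
            )

        # sequencing errors at non-variant positions
        for rd in reads:
            for k, p in enumerate(range(rd["start"], rd["end"])):
                if p in variant_positions or seq[p] not in "ACGT":
                    continue
                q = rd["quals"][k]
                if rng.random() < 10.0 ** (-q / 10.0):
                    rd["alts"][p] = _ALT[seq[p]][int(rng.integers(0, 3))]

        # emit columns
        active: list[int] = []
        for pos0 in range(span):
            starting = [ri for ri in coverage[pos0] if reads[ri]["start"] == pos0]
            active = [ri for ri in active if reads[ri]["end"] > pos0] + starting
            if not active:
                continue
            bases_s = []
            quals_s = []
            for ri in active:
                rd = reads[ri]
                base = rd["alts"].get(pos0)
                ch = base if base is not None else "."
                if rd["start"] == pos0:
                    ch = "^~" + ch
                if rd["end"] == pos0 + 1:
                    ch = ch + "$"
                bases_s.append(ch)
                quals_s.append(chr(int(rd["quals"][pos0 - rd["start"]]) + 33))
            out.write(
                f"{contig_id}\t{pos0 + 1}\t{seq[pos0]}\t{len(active)}\t"
                f"{''.join(bases_s)}\t{''.join(quals_s)}\n"
            )

    truth = pd.DataFrame(
        truth_rows,
        columns=["contig_id", "pos", "ref", "alt", "depth", "alt_count", "recoverable"],
    ).sort_values(["contig_id", "pos"]).reset_index(drop=True)
    return out.getvalue(), truth


def write_fasta(text: str, path: str) -> None:
    with open(path, "w") as out:
        out.write(text)


def write_blast_tab(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False, header=False, float_format="%.6g")
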