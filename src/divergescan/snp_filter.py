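"""Neighborhood Quality Standard (NQS) biallelic SNP filtering.

Input is samtools-style 6-column text pileup (contig, 1-based position,
reference base, depth, read bases, base qualities).  Read-base strings use
``.`` for a match, ``ACGT`` for a mismatch, ``*`` for a deletion gap,
``^X`` before a read's first base and ``$`` after its last.  Reads are
tracked across columns so that each observation carries its within-read
neighborhood (the centered quality window required by NQS).

An observation passes NQS when its central quality, windowed mean quality,
and windowed mismatch+gap count clear the thresholds; a column yields a
call when the passing depth is in range, exactly two alleles (reference
plus one alternative) are seen among passing reads, and the alternative
fraction clears the minimum variant frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "SnpFilterParams",
    "Observation",
    "PileupColumn",
    "SnpCall",
    "parse_pileup",
    "call_snps",
    "snp_density",
    "write_snp_table",
    "write_vcf",
]


@dataclass(frozen=True)
class SnpFilterParams:
    window: int = 11
    min_central_qual: int = 20
    min_avg_qual: int = 20
    max_gap_mismatch: int = 2
    min_coverage: int = 10
    max_coverage: int = 60
    min_variant_freq: float = 0.35
    biallelic_only: bool = True

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if not 0.0 < self.min_variant_freq <= 0.5:
            raise ValueError("min_variant_freq must lie in (0, 0.5]")
        if self.min_coverage > self.max_coverage:
            raise ValueError("min_coverage must not exceed max_coverage")


@dataclass(frozen=True)
class Observation:
    """One read's evidence at one column."""

    read_id: int
    base: str  # '.', 'A', 'C', 'G', 'T', or '*'
    qual: int

    @property
    def is_gap(self) -> bool:
        return self.base == "*"

    @property
    def is_mismatch(self) -> bool:
        return self.base in "ACGT"


@dataclass
class PileupColumn:
    contig_id: str
    pos: int  # 1-based
    ref_base: str
    observations: list[Observation]

    @property
    def depth(self) -> int:
        return len(self.observations)


@dataclass(frozen=True)
class SnpCall:
    contig_id: str
    pos: int
    ref: str
    alt: str
    depth: int
    alt_fraction: float
    passing_read_count: int


def parse_pileup(lines: Iterable[str]) -> Iterator[PileupColumn]:
    """Stream pileup columns, assigning stable per-read identifiers.

    Ordering contract (matched by the synthetic generator): continuing reads
    come first in their existing order; reads starting at the column are
    appended, each introduced by ``^`` + mapping-quality char; ``$`` follows
    a read's final base.
    """
    active: list[int] = []  # read ids in column order, per contig
    next_read = 0
    current_contig: str | None = None
    last_pos = 0
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) != 6:
            raise ValueError(f"pileup line {lineno}: expected 6 columns, got {len(fields)}")
        contig, pos_s, ref, depth_s, bases, quals = fields
        try:
            pos = int(pos_s)
            depth = int(depth_s)
        except ValueError as exc:
            raise ValueError(f"pileup line {lineno}: {exc}") from exc
        if contig != current_contig:
            current_contig = contig
            active = []
            last_pos = 0
        elif pos <= last_pos:
            raise ValueError(
                f"pileup line {lineno}: unsorted input at {contig}:{pos}"
            )
        last_pos = pos

        obs: list[Observation] = []
        ending: list[int] = []
        cont_idx = 0
        i = 0
        while i < len(bases):
            ch = bases[i]
            if ch == "^":
                # new read: '^' + mapq char + first base; claim a fresh id
                if i + 2 >= len(bases):
                    raise ValueError(f"pileup line {lineno}: dangling '^'")
                base = bases[i + 2]
                i += 3
                read_id = next_read
                next_read += 1
                active.append(read_id)
            else:
                base = ch
                i += 1
                if cont_idx >= len(active):
                    raise ValueError(
                        f"pileup line {lineno}: more observations than tracked reads "
                        f"at {contig}:{pos}"
                    )
                read_id = active[cont_idx]
                cont_idx += 1
            if base.upper() not in ".ACGTN*":
                raise ValueError(
                    f"pileup line {lineno}: unexpected base symbol {base!r}"
                )
            if i < len(bases) and bases[i] == "$":
                ending.append(read_id)
                i += 1
            obs.append(Observation(read_id, base.upper(), ord(quals[len(obs)]) - 33))
        if len(obs) != depth:
            raise ValueError(
                f"pileup line {lineno}: depth field {depth} != {len(obs)} observations"
            )
        if len(quals) != len(obs):
            raise ValueError(
                f"pileup line {lineno}: quality string length mismatch"
            )
        active = [r for r in active if r not in ending]
        yield PileupColumn(contig, pos, ref, obs)


def _read_tracks(
    columns: Sequence[PileupColumn],
) -> dict[int, list[tuple[int, Observation]]]:
    """Per-read ordered list of (column index, observation)."""
    tracks: dict[int, list[tuple[int, Observation]]] = {}
    for ci, col in enumerate(columns):
        for ob in col.observations:
            tracks.setdefault(ob.read_id, []).append((ci, ob))
    return tracks


def _nqs_pass(
    window_obs: Sequence[Observation], center: Observation, params: SnpFilterParams
) -> bool:
    if center.qual < params.min_central_qual:
        return False
    mean_q = sum(ob.qual for ob in window_obs) / len(window_obs)
    if mean_q < params.min_avg_qual:
        return False
    # mismatches/gaps in the flanking neighborhood; the central base itself
    # (the candidate variant) is not counted against the read
    bad = sum(
        1 for ob in window_obs if (ob.is_mismatch or ob.is_gap) and ob is not center
    )
    return bad <= params.max_gap_mismatch


def call_snps(
    columns: Iterable[PileupColumn] | Iterable[str],
    params: SnpFilterParams = SnpFilterParams(),
) -> list[SnpCall]:
    """Apply the NQS filter to a pileup and return biallelic SNP calls.

    Accepts parsed columns or raw pileup lines.  Columns whose reference is
    ``N`` or lowercase (repeat-masked) are skipped.  Coverage gates apply to
    reads passing the per-read NQS window test.
    """
    cols = list(columns)
    if cols and isinstance(cols[0], str):
        cols = list(parse_pileup(cols))
    half = (params.window - 1) // 2

    calls: list[SnpCall] = []
    # group columns per contig, preserving order
    by_contig: dict[str, list[PileupColumn]] = {}
    for col in cols:
        by_contig.setdefault(col.contig_id, []).append(col)

    for contig_cols in by_contig.values():
        tracks = _read_tracks(contig_cols)
        # read_id -> {column index -> position within track}
        index_in_track = {
            rid: {ci: k for k, (ci, _) in enumerate(track)}
            for rid, track in tracks.items()
        }
        for ci, col in enumerate(contig_cols):
            if col.ref_base == "N" or col.ref_base.islower():
                continue
            passing: list[Observation] = []
            for ob in col.observations:
                track = tracks[ob.read_id]
                k = index_in_track[ob.read_id][ci]
                lo = max(0, k - half)
                hi = min(len(track), k + half + 1)
                window_obs = [o for _, o in track[lo:hi]]
                if _nqs_pass(window_obs, ob, params):
                    passing.append(ob)
            non_gap = [ob for ob in passing if not ob.is_gap]
            depth = len(non_gap)
            if depth < params.min_coverage or depth > params.max_coverage:
                continue
            alleles = {col.ref_base.upper() if ob.base == "." else ob.base for ob in non_gap}
            if params.biallelic_only and len(alleles) != 2:
                continue
            ref = col.ref_base.upper()
            if ref not in alleles:
                continue
            (alt,) = alleles - {ref}
            alt_count = sum(
                1 for ob in non_gap if (ref if ob.base == "." else ob.base) == alt
            )
            alt_fraction = alt_count / depth
            if alt_fraction < params.min_variant_freq:
                continue
            calls.append(
                SnpCall(col.contig_id, col.pos, ref, alt, depth, alt_fraction, depth)
            )
    return calls


def snp_density(
    calls: Sequence[SnpCall],
    contig_lengths: dict[str, int],
    contig_chromosome: dict[str, str] | None = None,
    excluded_chromosomes: frozenset[str] = frozenset({"Z", "W", "chrZ", "chrW"}),
) -> dict:
    """SNP density per kb overall and with sex chromosomes excluded.

    ``contig_chromosome`` maps contigs to chromosome labels; unmapped
    contigs are summarised separately and excluded from the autosomal
    figure.  Density = calls / mapped non-excluded bp * 1000.
    """
    for call in calls:
        if call.contig_id not in contig_lengths:
            raise ValueError(f"call on unknown contig {call.contig_id!r}")
    contig_chromosome = contig_chromosome or {}

    def _class(contig: str) -> str:
        chrom = contig_chromosome.get(contig)
        if chrom is None:
            return "unmapped"
        return "excluded" if chrom in excluded_chromosomes else "autosomal"

    counts = {"autosomal": 0, "excluded": 0, "unmapped": 0}
    bp = {"autosomal": 0, "excluded": 0, "unmapped": 0}
    for contig, length in contig_lengths.items():
        bp[_class(contig)] += length
    for call in calls:
        counts[_class(call.contig_id)] += 1

    def _density(n: int, total: int) -> float:
        return n / total * 1000.0 if total else 0.0

    total_bp = sum(bp.values())
    return {
        "overall_per_kb": _density(len(calls), total_bp),
        "autosomal_per_kb": _density(counts["autosomal"], bp["autosomal"]),
        "excluded_calls": counts["excluded"],
        "unmapped_calls": counts["unmapped"],
        "autosomal_bp": bp["autosomal"],
        "n_calls": len(calls),
    }


def write_snp_table(calls: Sequence[SnpCall], path: str) -> None:
    table = pd.DataFrame(
        [
            (c.contig_id, c.pos, c.ref, c.alt, c.depth, round(c.alt_fraction, 6))
            for c in calls
        ],
        columns=["contig", "pos", "ref", "alt", "depth", "freq"],
    )
    table.to_csv(path, sep="\t", index=False)


def write_vcf(calls: Sequence[SnpCall], path: str, sample: str = "SAMPLE") -> None:
    """Minimal VCF 4.2 writer with unphased heterozygous genotypes."""
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        out.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        out.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">\n')
        out.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for c in calls:
            info = f"DP={c.depth};AF={c.alt_fraction:.4f}"
            out.write(
                f"{c.contig_id}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t{info}\tGT\t0/1\n"
            )
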