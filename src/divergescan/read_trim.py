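"""Quality, ambiguity, and adapter trimming of sequencing reads.

Quality trimming uses a running-sum (modified-Mott) scheme: every base
contributes ``limit - P_error(Q)``; the running sum is reset to zero whenever
it drops below zero, and the retained segment runs from the first positive
position after the last reset up to the (leftmost) maximum of the running
sum.  This is exactly the maximum-sum contiguous substring of the per-base
scores.  Reads whose running sum never exceeds zero are discarded.

Ambiguity trimming removes terminal runs of ``N``; adapter trimming removes
Smith-Waterman matches to user-supplied adapters together with everything
3' of the match.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, TextIO

from Bio import SeqIO

__all__ = [
    "QualityRead",
    "TrimSpec",
    "TrimResult",
    "phred_to_perror",
    "quality_trim",
    "ambiguity_trim",
    "adapter_trim",
    "trim_read",
    "trim_fastq",
    "smith_waterman",
]

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class QualityRead:
    """A read with per-base Phred scores."""

    read_id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"{self.read_id}: bases and quals differ in length "
                f"({len(self.bases)} vs {len(self.quals)})"
            )
        if any(q < 0 or q > 60 for q in self.quals):
            raise ValueError(f"{self.read_id}: Phred scores must lie in [0, 60]")
        bad = set(self.bases.upper()) - _VALID_BASES
        if bad:
            raise ValueError(f"{self.read_id}: invalid bases {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class TrimSpec:
    """Parameters for the three trimming stages."""

    limit: float = 0.05
    max_end_n: int = 3
    adapters: tuple[str, ...] = ()
    sw_match: int = 1
    sw_mismatch: int = -2
    sw_gap: int = -3
    sw_min_score: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.limit < 1.0:
            raise ValueError("limit must lie strictly in (0, 1)")
        if self.max_end_n < 0:
            raise ValueError("max_end_n must be >= 0")
        if self.sw_min_score <= 0:
            raise ValueError("sw_min_score must be positive")
        for adapter in self.adapters:
            if not adapter or set(adapter.upper()) - set("ACGT"):
                raise ValueError(f"adapter {adapter!r} must be a non-empty ACGT string")


@dataclass
class TrimResult:
    """Outcome of trimming: half-open kept interval into the original read."""

    read_id: str
    kept_start: int
    kept_end: int
    discarded: bool
    stage_log: tuple[str, ...] = field(default_factory=tuple)

    @property
    def kept_interval(self) -> tuple[int, int]:
        return (self.kept_start, self.kept_end)

    @property
    def kept_length(self) -> int:
        return self.kept_end - self.kept_start


def phred_to_perror(q: int | float) -> float:
    """Error probability for a Phred score: ``10**(-q/10)``."""
    if q < 0:
        raise ValueError(f"Phred score must be non-negative, got {q}")
    return 10.0 ** (-q / 10.0)


def quality_trim(read: QualityRead, spec: TrimSpec) -> TrimResult:
    """Running-sum quality trim.

    Per base the score is ``limit - P_error``; the running sum resets to zero
    when it would go non-positive.  The kept segment ends at the leftmost
    maximum of the running sum and starts just after the preceding reset;
    its score sum equals the maximum over all contiguous substrings.
    A read whose running sum never becomes positive is discarded.
    """
    if len(read) == 0:
        return TrimResult(read.read_id, 0, 0, discarded=True, stage_log=("quality",))

    best = 0.0
    best_start = 0
    best_end = 0
    run = 0.0
    seg_start = 0
    for i, q in enumerate(read.quals):
        run += spec.limit - phred_to_perror(q)
        if run <= 0.0:
            run = 0.0
            seg_start = i + 1
        elif run > best:
            best = run
            best_start = seg_start
            best_end = i + 1

    if best <= 0.0:
        return TrimResult(read.read_id, 0, 0, discarded=True, stage_log=("quality",))
    stages = ("quality",) if (best_start, best_end) != (0, len(read)) else ()
    return TrimResult(read.read_id, best_start, best_end, discarded=False, stage_log=stages)


def ambiguity_trim(read: QualityRead, spec: TrimSpec) -> TrimResult:
    """Remove terminal runs of ``N`` entirely.

    ``max_end_n`` caps the tolerated run length: longer terminal runs (and
    internal N counts above the cap) additionally flag the read as
    ``ambiguity_excess``.  Internal Ns are never excised, preserving
    coordinates.
    """
    bases = read.bases.upper()
    n = len(bases)
    lead = 0
    while lead < n and bases[lead] == "N":
        lead += 1
    trail = 0
    while trail < n - lead and bases[n - 1 - trail] == "N":
        trail += 1
    start, end = lead, n - trail
    stages: list[str] = []
    if lead or trail:
        stages.append("ambiguity")
    internal_n = bases[start:end].count("N")
    if lead > spec.max_end_n or trail > spec.max_end_n or internal_n > spec.max_end_n:
        stages.append("ambiguity_excess")
    discarded = start >= end
    if discarded:
        start = end = 0
    return TrimResult(read.read_id, start, end, discarded, tuple(stages))


def smith_waterman(
    seq: str, pattern: str, match: int = 1, mismatch: int = -2, gap: int = -3
) -> tuple[int, int, int]:
    """Best local alignment of ``pattern`` within ``seq``.

    Returns ``(score, start, end)`` where ``[start, end)`` is the spanned
    interval of ``seq``.  Linear gap penalty; ties resolve to the leftmost,
    shortest-spanning alignment.
    """
    seq = seq.upper()
    pattern = pattern.upper()
    n, m = len(seq), len(pattern)
    best = 0
    best_span = (0, 0)
    # H[j]: score ending at current seq position i, pattern position j.
    prev = [0] * (m + 1)
    prev_origin = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        cur_origin = [i] * (m + 1)
        for j in range(1, m + 1):
            sub = match if seq[i - 1] == pattern[j - 1] else mismatch
            diag = prev[j - 1] + sub
            up = prev[j] + gap  # gap in pattern (consume seq base)
            left = cur[j - 1] + gap  # gap in seq (consume pattern base)
            score = max(diag, up, left, 0)
            if score == 0:
                cur[j] = 0
                cur_origin[j] = i
                continue
            if score == diag:
                origin = prev_origin[j - 1]
            elif score == up:
                origin = prev_origin[j]
            else:
                origin = cur_origin[j - 1]
            cur[j] = score
            cur_origin[j] = origin
            if score > best:
                best = score
                best_span = (origin, i)
        prev, prev_origin = cur, cur_origin
    return best, best_span[0], best_span[1]


def adapter_trim(read: QualityRead, spec: TrimSpec) -> TrimResult:
    """Remove adapter matches and all bases 3' of them.

    Each adapter is locally aligned against the read; any match scoring at
    least ``sw_min_score`` removes the matched span together with everything
    downstream.  Repeats until no adapter matches.
    """
    if not spec.adapters:
        return TrimResult(read.read_id, 0, len(read), discarded=False)
    end = len(read)
    hit_any = False
    while True:
        cut = None
        for adapter in spec.adapters:
            score, start, _ = smith_waterman(
                read.bases[:end], adapter, spec.sw_match, spec.sw_mismatch, spec.sw_gap
            )
            if score >= spec.sw_min_score and (cut is None or start < cut):
                cut = start
        if cut is None:
            break
        hit_any = True
        end = cut
        if end == 0:
            break
    discarded = end == 0
    stages = ("adapter",) if hit_any else ()
    return TrimResult(read.read_id, 0, 0 if discarded else end, discarded, stages)


def _slice(read: QualityRead, start: int, end: int) -> QualityRead:
    return QualityRead(read.read_id, read.bases[start:end], read.quals[start:end])


def trim_read(read: QualityRead, spec: TrimSpec) -> TrimResult:
    """Full trim pipeline: quality, then ambiguity, then adapter removal,
    iterated until the kept interval is stable (one pass can expose a new
    low-quality or ambiguous end; iterating makes the pipeline idempotent).

    The returned interval indexes the *original* read.
    """
    result = _trim_read_once(read, spec)
    stages = list(result.stage_log)
    while not result.discarded:
        sliced = _slice(read, result.kept_start, result.kept_end)
        again = _trim_read_once(sliced, spec)
        stages.extend(again.stage_log)
        if again.discarded:
            result = TrimResult(read.read_id, 0, 0, True, ())
            break
        if again.kept_interval == (0, len(sliced)):
            break
        result = TrimResult(
            read.read_id,
            result.kept_start + again.kept_start,
            result.kept_start + again.kept_end,
            False,
            (),
        )
    return TrimResult(
        read.read_id,
        result.kept_start,
        result.kept_end,
        result.discarded,
        tuple(dict.fromkeys(stages)),
    )


def _trim_read_once(read: QualityRead, spec: TrimSpec) -> TrimResult:
    stages: list[str] = []
    qres = quality_trim(read, spec)
    stages.extend(qres.stage_log)
    if qres.discarded:
        return TrimResult(read.read_id, 0, 0, True, tuple(stages))
    offset = qres.kept_start
    current = _slice(read, qres.kept_start, qres.kept_end)

    ares = ambiguity_trim(current, spec)
    stages.extend(ares.stage_log)
    if ares.discarded:
        return TrimResult(read.read_id, 0, 0, True, tuple(dict.fromkeys(stages)))
    offset += ares.kept_start
    current = _slice(current, ares.kept_start, ares.kept_end)

    tres = adapter_trim(current, spec)
    stages.extend(tres.stage_log)
    stages = list(dict.fromkeys(stages))
    if tres.discarded:
        return TrimResult(read.read_id, 0, 0, True, tuple(stages))
    return TrimResult(
        read.read_id, offset + tres.kept_start, offset + tres.kept_end, False, tuple(stages)
    )


def _iter_fastq(handle: TextIO | str) -> Iterator[QualityRead]:
    try:
        for rec in SeqIO.parse(handle, "fastq"):
            quals = tuple(rec.letter_annotations["phred_quality"])
            yield QualityRead(rec.id, str(rec.seq).upper(), quals)
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ record: {exc}") from exc


def trim_fastq(
    in_path: str,
    out_fastq: str,
    out_log: str,
    spec: TrimSpec,
) -> int:
    """Trim every read in a FASTQ file.

    Discarded reads are omitted from the output FASTQ but still logged.
    Returns the number of reads written.
    """
    written = 0
    with open(in_path) as src, open(out_fastq, "w") as fq, open(out_log, "w", newline="") as log:
        writer = csv.writer(log, delimiter="\t", lineterminator="\n")
        writer.writerow(["read_id", "kept_start", "kept_end", "discarded", "stages"])
        for read in _iter_fastq(src):
            res = trim_read(read, spec)
            writer.writerow(
                [
                    res.read_id,
                    res.kept_start,
                    res.kept_end,
                    int(res.discarded),
                    ",".join(res.stage_log),
                ]
            )
            if res.discarded:
                continue
            bases = read.bases[res.kept_start : res.kept_end]
            quals = read.quals[res.kept_start : res.kept_end]
            qstr = "".join(chr(q + 33) for q in quals)
            fq.write(f"@{read.read_id}\n{bases}\n+\n{qstr}\n")
            written += 1
    return written
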