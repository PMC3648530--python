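"""Ingestion of BLAST tabular (outfmt 6) alignments.

Provides typed parsing, the E-value step-down top-hit workflow, deterministic
tie-breaking, unique-chromosome classification, and per-chromosome summary
statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "BLAST6_COLUMNS",
    "AlignmentHit",
    "parse_blast_tab",
    "select_top_hit",
    "evalue_stepdown",
    "classify_unique_chromosome",
    "per_chromosome_summary",
    "load_contigs",
]

BLAST6_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)

_DTYPES = {
    "qseqid": str,
    "sseqid": str,
    "pident": float,
    "length": int,
    "mismatch": int,
    "gapopen": int,
    "qstart": int,
    "qend": int,
    "sstart": int,
    "send": int,
    "evalue": float,
    "bitscore": float,
}


@dataclass(frozen=True)
class AlignmentHit:
    """One BLAST tabular record."""

    qseqid: str
    sseqid: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        _validate_row(self.__dict__, context=self.qseqid)


def _validate_row(row: dict, context: str) -> None:
    if not 0.0 < row["pident"] <= 100.0:
        raise ValueError(f"{context}: pident {row['pident']} outside (0, 100]")
    if row["length"] < 1:
        raise ValueError(f"{context}: alignment length must be >= 1")
    if row["qstart"] > row["qend"]:
        raise ValueError(f"{context}: qstart > qend")
    if row["evalue"] < 0:
        raise ValueError(f"{context}: negative evalue")
    if row["bitscore"] <= 0:
        raise ValueError(f"{context}: bitscore must be positive")


def parse_blast_tab(path: str) -> pd.DataFrame:
    """Parse a 12-column BLAST outfmt-6 TSV into a typed, validated table.

    Row order is preserved.  Malformed rows raise ``ValueError`` naming the
    offending line number.
    """
    rows: list[list] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 columns, found {len(fields)}"
                )
            try:
                typed = [
                    _DTYPES[col](value)
                    for col, value in zip(BLAST6_COLUMNS, fields)
                ]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            record = dict(zip(BLAST6_COLUMNS, typed))
            try:
                _validate_row(record, context=f"{path}:{lineno}")
            except ValueError:
                raise
            rows.append(typed)
    table = pd.DataFrame(rows, columns=list(BLAST6_COLUMNS))
    if table.empty:
        table = pd.DataFrame({c: pd.Series(dtype=t) for c, t in _DTYPES.items()})
    return table


def _hit_sort_key(row) -> tuple:
    # evalue ascending, bitscore/length descending, then a deterministic
    # total order on (sseqid, sstart).
    return (row.evalue, -row.bitscore, -row.length, row.sseqid, row.sstart)


def select_top_hit(hits: pd.DataFrame) -> pd.Series | None:
    """Best hit of one query: minimum E-value, ties broken by bitscore, then
    alignment length, then lexicographically by (sseqid, sstart).

    Returns ``None`` for an empty hit table (absence, not an error).
    """
    if hits.empty:
        return None
    best = min(hits.itertuples(index=True), key=_hit_sort_key)
    return hits.loc[best.Index]


def top_hits(table: pd.DataFrame) -> pd.DataFrame:
    """Single-pass top-hit selection for every query in the table."""
    if table.empty:
        return table.copy()
    order = table.assign(
        _key=list(zip(table.evalue, -table.bitscore, -table.length, table.sseqid, table.sstart))
    )
    idx = order.groupby("qseqid", sort=False)["_key"].idxmin()
    return table.loc[sorted(idx)].reset_index(drop=True)


def evalue_stepdown(
    table: pd.DataFrame,
    cutoffs: Sequence[float | None] = (1e-50, 1e-25, None),
) -> pd.DataFrame:
    """Staged top-hit selection with relaxing E-value cutoffs.

    Stage *k* resolves every query whose best hit passes cutoff *k*;
    unresolved queries fall through to the next stage.  A ``None`` cutoff
    accepts everything.  The result is provably identical to single-pass
    top-hit selection (the best hit of a query passing an earlier cutoff is
    its global best); both routes are kept for cross-checking.
    """
    numeric = [c for c in cutoffs if c is not None]
    if any(b <= a for a, b in zip(numeric, numeric[1:])):
        raise ValueError(f"cutoffs must be strictly relaxing, got {list(cutoffs)}")
    if numeric and cutoffs[-1] is not None:
        pass  # a final numeric cutoff is allowed; queries above it stay unresolved
    remaining = table
    resolved: list[pd.DataFrame] = []
    for cutoff in cutoffs:
        if remaining.empty:
            break
        stage = remaining if cutoff is None else remaining[remaining.evalue <= cutoff]
        stage_tops = top_hits(stage)
        resolved.append(stage_tops)
        done = set(stage_tops.qseqid)
        remaining = remaining[~remaining.qseqid.isin(done)]
    if not resolved:
        return table.iloc[0:0].copy()
    out = pd.concat(resolved, ignore_index=True)
    return out.sort_values("qseqid", kind="mergesort").reset_index(drop=True)


def classify_unique_chromosome(table: pd.DataFrame) -> pd.Series:
    """Per query: True iff every retained hit lands on a single subject.

    Uses all hits present in ``table`` for the query, not only the top hit.
    """
    return table.groupby("qseqid")["sseqid"].nunique() == 1


def per_chromosome_summary(tophits: pd.DataFrame) -> pd.DataFrame:
    """Per-subject summary of top hits: contig count, median/mean identity,
    median alignment length."""
    if tophits.empty:
        raise ValueError("cannot summarise an empty top-hit table")
    grouped = tophits.groupby("sseqid")
    out = pd.DataFrame(
        {
            "n_contigs": grouped["qseqid"].nunique(),
            "median_pident": grouped["pident"].median(),
            "mean_pident": grouped["pident"].mean(),
            "median_length": grouped["length"].median(),
        }
    ).reset_index()
    return out.sort_values("sseqid").reset_index(drop=True)


def load_contigs(path: str) -> pd.DataFrame:
    """Per-contig length and GC fraction (G+C over non-N bases) from FASTA."""
    ids: list[str] = []
    lengths: list[int] = []
    gcs: list[float] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate contig identifier {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        denom = len(seq) - seq.count("N")
        gc = (seq.count("G") + seq.count("C")) / denom if denom else 0.0
        ids.append(rec.id)
        lengths.append(len(seq))
        gcs.append(gc)
    return pd.DataFrame({"contig_id": ids, "length": lengths, "gc": gcs})
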