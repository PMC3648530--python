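"""Composite divergence statistic and percentile outlier calling.

The per-contig statistic is the top alignment's fractional identity divided
by its alignment length, ``(pident/100) / length``.  Small values indicate
extended conservation (high identity over long alignments), large values
indicate putative divergence — the maximum attainable for an alignment of at
least 19 bp is ``1/19 = 0.052631579``, realised by a 19-bp perfect match.

Outliers are the scores equal to or more extreme than nearest-rank
percentile bounds of the ordered distribution (defaults 99.98 / 0.02).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OutlierParams",
    "OutlierReport",
    "composite_score",
    "score_table",
    "nearest_rank",
    "call_outliers",
    "lilliefors_normality",
    "lilliefors_null_distribution",
    "recompute_conserved_multi",
    "refute_outliers",
]


def composite_score(pident: float, length: int) -> float:
    """Fractional identity per aligned base: ``(pident/100) / length``."""
    if length <= 0:
        raise ValueError(f"alignment length must be positive, got {length}")
    if not 0.0 < pident <= 100.0:
        raise ValueError(f"pident must lie in (0, 100], got {pident}")
    return (pident / 100.0) / length


def score_table(tophits: pd.DataFrame) -> pd.DataFrame:
    """Composite score for every top hit; columns contig_id, score."""
    if (tophits["length"] <= 0).any():
        raise ValueError("alignment lengths must be positive")
    scores = (tophits["pident"] / 100.0) / tophits["length"]
    return pd.DataFrame({"contig_id": tophits["qseqid"].values, "score": scores.values})


@dataclass(frozen=True)
class OutlierParams:
    upper_percentile: float = 99.98
    lower_percentile: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 < self.lower_percentile < self.upper_percentile < 100.0:
            raise ValueError(
                "percentiles must satisfy 0 < lower < upper < 100, got "
                f"{self.lower_percentile}/{self.upper_percentile}"
            )


@dataclass
class OutlierReport:
    lower_bound: float
    upper_bound: float
    conserved: frozenset[str]
    diverged: frozenset[str]
    n_total: int

    @property
    def outliers(self) -> frozenset[str]:
        return self.conserved | self.diverged

    def captured_fraction(self, scores: Sequence[float]) -> float:
        """Fraction of scores inside the closed interval [lower, upper]."""
        arr = np.asarray(scores, dtype=float)
        inside = (arr >= self.lower_bound) & (arr <= self.upper_bound)
        return float(inside.mean())


def nearest_rank(sorted_values: np.ndarray, percentile: float) -> float:
    """Nearest-rank percentile: value at index ``ceil(p/100 * n)`` (1-based)
    of the ascending-ordered sample."""
    n = len(sorted_values)
    rank = max(1, math.ceil(percentile / 100.0 * n))
    return float(sorted_values[rank - 1])


MIN_SCORES = 100


def call_outliers(
    scores: pd.DataFrame | dict[str, float],
    params: OutlierParams = OutlierParams(),
    min_scores: int = MIN_SCORES,
) -> OutlierReport:
    """Call conserved/diverged outliers by the equal-or-more-extreme rule.

    ``scores`` maps contig_id -> composite score (DataFrame with columns
    contig_id/score, or a mapping).  Conserved: score <= lower bound;
    diverged: score >= upper bound, where bounds are nearest-rank
    percentiles of the ordered distribution.
    """
    if isinstance(scores, dict):
        table = pd.DataFrame(
            {"contig_id": list(scores), "score": list(scores.values())}
        )
    else:
        table = scores
    n = len(table)
    if n < min_scores:
        raise ValueError(f"need at least {min_scores} scores, got {n}")
    values = np.sort(table["score"].to_numpy(dtype=float))
    lower = nearest_rank(values, params.lower_percentile)
    upper = nearest_rank(values, params.upper_percentile)
    if lower == upper:
        raise ValueError("degenerate distribution: percentile bounds coincide")
    conserved = frozenset(table.loc[table["score"] <= lower, "contig_id"])
    diverged = frozenset(table.loc[table["score"] >= upper, "contig_id"])
    return OutlierReport(lower, upper, conserved, diverged, n)


def _ks_statistic_normal(z: np.ndarray) -> float:
    """Two-sided KS distance of a standardised sample from N(0,1)."""
    z = np.sort(z)
    n = len(z)
    cdf = stats.norm.cdf(z)
    d_plus = np.max(np.arange(1, n + 1) / n - cdf)
    d_minus = np.max(cdf - np.arange(0, n) / n)
    return float(max(d_plus, d_minus))


def lilliefors_null_distribution(
    n: int, n_mc: int = 10_000, seed: int = 0
) -> np.ndarray:
    """Monte Carlo null distribution of the Lilliefors D statistic for
    samples of size ``n`` (mean and sd estimated from each sample)."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_mc)
    grid = np.arange(1, n + 1) / n
    grid_lo = np.arange(0, n) / n
    block = max(1, min(n_mc, 2_000_000 // max(n, 1)))
    done = 0
    while done < n_mc:
        k = min(block, n_mc - done)
        samples = rng.standard_normal((k, n))
        mu = samples.mean(axis=1, keepdims=True)
        sd = samples.std(axis=1, ddof=1, keepdims=True)
        z = np.sort((samples - mu) / sd, axis=1)
        cdf = stats.norm.cdf(z)
        d = np.maximum(
            (grid - cdf).max(axis=1), (cdf - grid_lo).max(axis=1)
        )
        out[done : done + k] = d
        done += k
    return out


def lilliefors_normality(
    scores: Sequence[float], n_mc: int = 10_000, seed: int = 0
) -> tuple[float, float]:
    """Lilliefors-corrected KS normality test.

    D is computed against a normal with mean/sd estimated from the sample;
    the p-value comes from a seeded Monte Carlo null (parameters estimated
    per replicate), ``p = (1 + #{D_null >= D}) / (n_mc + 1)``.
    """
    x = np.asarray(scores, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError(f"need at least 10 observations, got {n}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance sample")
    d = _ks_statistic_normal((x - x.mean()) / sd)
    null = lilliefors_null_distribution(n, n_mc=n_mc, seed=seed)
    p = (1 + int(np.sum(null >= d - 1e-12))) / (n_mc + 1)
    return d, float(p)


def recompute_conserved_multi(hits: pd.DataFrame) -> float:
    """Pooled composite score over non-overlapping syntenic hits of one
    contig: summed identical bases divided by the squared summed alignment
    length (pooled identity fraction per total aligned base).

    With a single hit this equals ``composite_score`` exactly; appending a
    hit whose identity fraction does not exceed the pooled fraction strictly
    decreases the score (conserved outliers become more extreme).
    """
    if hits.empty:
        raise ValueError("need at least one hit")
    intervals = sorted(zip(hits["qstart"], hits["qend"]))
    for (s1, e1), (s2, _) in zip(intervals, intervals[1:]):
        if s2 <= e1:
            raise ValueError(
                f"overlapping query intervals ({s1},{e1}) and ({s2},...)"
            )
    ident = float(np.sum(hits["pident"].to_numpy() / 100.0 * hits["length"].to_numpy()))
    total = float(hits["length"].sum())
    return ident / total**2


def refute_outliers(
    report: OutlierReport,
    scores: pd.DataFrame,
    alternate_hits: pd.DataFrame,
) -> tuple[OutlierReport, pd.DataFrame]:
    """Drop diverged outliers contradicted by stronger alternate alignments.

    A diverged outlier is removed iff some alternate hit for it is longer
    and more significant (lower E-value) than its original top hit and the
    alternate hit's composite score falls strictly inside
    ``(lower_bound, upper_bound)``.  Returns the filtered report and an
    evidence log of removals.
    """
    originals = scores.set_index("contig_id")
    if {"length", "evalue"} - set(scores.columns):
        raise ValueError("scores table must carry length and evalue columns")
    removals: list[dict] = []
    removed: set[str] = set()
    for contig in sorted(report.diverged):
        if contig not in originals.index:
            continue
        orig = originals.loc[contig]
        alts = alternate_hits[alternate_hits["qseqid"] == contig]
        for alt in alts.itertuples():
            if alt.length <= orig["length"] or alt.evalue >= orig["evalue"]:
                continue
            alt_score = composite_score(alt.pident, alt.length)
            if report.lower_bound < alt_score < report.upper_bound:
                removed.add(contig)
                removals.append(
                    {
                        "contig_id": contig,
                        "alt_sseqid": alt.sseqid,
                        "alt_length": alt.length,
                        "alt_evalue": alt.evalue,
                        "alt_score": alt_score,
                    }
                )
                break
    evidence = pd.DataFrame(
        removals,
        columns=["contig_id", "alt_sseqid", "alt_length", "alt_evalue", "alt_score"],
    )
    filtered = OutlierReport(
        report.lower_bound,
        report.upper_bound,
        report.conserved,
        frozenset(report.diverged - removed),
        report.n_total,
    )
    return filtered, evidence
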