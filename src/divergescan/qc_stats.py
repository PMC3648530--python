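"""Quality-control battery for the divergence analysis.

Pairwise Pearson/Spearman correlations among contig properties, overlap of
contig-size percentile outliers with divergence outliers, and the 2x2
chi-square SNP-enrichment test between outlier classes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .divergence import OutlierParams, OutlierReport, call_outliers

__all__ = [
    "pairwise_correlations",
    "size_outlier_overlap",
    "snp_enrichment_chisq",
    "EnrichmentResult",
]

QC_VARIABLES = ("contig_size", "gc", "pident", "alignment_length")


def pairwise_correlations(
    table: pd.DataFrame, variables: tuple[str, ...] = QC_VARIABLES
) -> pd.DataFrame:
    """Pearson r and Spearman rho (average-rank ties) for every unordered
    variable pair.  Constant columns yield NaN coefficients."""
    missing = set(variables) - set(table.columns)
    if missing:
        raise ValueError(f"table lacks columns: {sorted(missing)}")
    clean = table[list(variables)].dropna()
    if len(clean) < 3:
        raise ValueError(f"need at least 3 complete rows, got {len(clean)}")
    rows = []
    for a, b in itertools.combinations(variables, 2):
        x = clean[a].to_numpy(dtype=float)
        y = clean[b].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            r = rho = float("nan")
        else:
            r = float(stats.pearsonr(x, y).statistic)
            rho = float(stats.spearmanr(x, y).statistic)
        rows.append({"var_a": a, "var_b": b, "pearson_r": r, "spearman_rho": rho, "n": len(clean)})
    return pd.DataFrame(rows)


def size_outlier_overlap(
    contig_sizes: dict[str, int] | pd.DataFrame,
    divergence_report: OutlierReport,
    divergence_contigs: frozenset[str] | set[str],
    params: OutlierParams = OutlierParams(),
) -> dict:
    """Intersect contig-size percentile outliers with divergence outliers.

    The same nearest-rank / equal-or-more-extreme rule used for the
    divergence statistic is applied to the ordered distribution of contig
    sizes.  ``divergence_contigs`` is the contig universe of the divergence
    analysis and must match the size table's universe.
    """
    if isinstance(contig_sizes, pd.DataFrame):
        sizes = dict(zip(contig_sizes["contig_id"], contig_sizes["length"]))
    else:
        sizes = dict(contig_sizes)
    universe = set(divergence_contigs)
    if set(sizes) != universe:
        raise ValueError(
            "contig universes differ between size table and divergence analysis"
        )
    size_report = call_outliers(
        {cid: float(v) for cid, v in sizes.items()}, params
    )
    size_outliers = size_report.outliers
    divergence_outliers = divergence_report.outliers
    overlap = size_outliers & divergence_outliers
    return {
        "size_outliers": size_outliers,
        "divergence_outliers": divergence_outliers,
        "overlap": overlap,
        "n_size_outliers": len(size_outliers),
        "n_divergence_outliers": len(divergence_outliers),
        "n_overlap": len(overlap),
    }


@dataclass(frozen=True)
class EnrichmentResult:
    conserved_snps: int
    conserved_bp: int
    diverged_snps: int
    diverged_bp: int
    chi2: float
    p_value: float
    valid: bool  # False when any expected cell < 1

    @property
    def table(self) -> np.ndarray:
        return np.array(
            [
                [self.conserved_snps, self.conserved_bp - self.conserved_snps],
                [self.diverged_snps, self.diverged_bp - self.diverged_snps],
            ],
            dtype=float,
        )


def snp_enrichment_chisq(
    conserved: tuple[int, int], diverged: tuple[int, int]
) -> EnrichmentResult:
    """Pearson chi-square (1 df, no continuity correction) on the 2x2 table
    {outlier class} x {SNP bp, non-SNP bp}.

    Each class is (snp_count, total_bp); every base pair is treated as a
    Bernoulli trial.
    """
    c_snp, c_bp = conserved
    d_snp, d_bp = diverged
    if c_bp <= 0 or d_bp <= 0:
        raise ValueError("total bp must be positive in both classes")
    if c_snp > c_bp or d_snp > d_bp:
        raise ValueError("snp count cannot exceed total bp")
    a, b = c_snp, c_bp - c_snp
    c, d = d_snp, d_bp - d_snp
    n = a + b + c + d
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    if col1 == 0 or col2 == 0:
        chi2 = 0.0
    else:
        chi2 = n * (a * d - b * c) ** 2 / (row1 * row2 * col1 * col2)
    p = float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    expected_min = min(
        row1 * col1, row1 * col2, row2 * col1, row2 * col2
    ) / n
    return EnrichmentResult(
        c_snp, c_bp, d_snp, d_bp, float(chi2), p, valid=expected_min >= 1.0
    )
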