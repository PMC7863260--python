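"""Genomic-control correction of GWAS test statistics using intergenic SNPs.

Population stratification, cryptic relatedness or over-correction can inflate
(or deflate) the empirical null distribution of association chi-square
statistics.  The inflation factor lambda_GC is estimated as the median
chi-square over putatively null SNPs divided by the median of the chi-square
distribution with one degree of freedom (0.4549364).  Intergenic SNPs — those
overlapping no annotated gene interval — stand in for the null set.  All
z-scores are then rescaled by 1/sqrt(lambda_GC) and p-values recomputed, which
leaves the ranking of SNPs unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sps

from .sumstats import SumStatsTable, p_from_z, z_from_p

logger = logging.getLogger(__name__)

#: Median of the chi-square distribution with 1 degree of freedom.
CHI2_1_MEDIAN = 0.4549364

#: Minimum number of intergenic SNPs for a stable median-based estimate.
MIN_INTERGENIC = 1000


@dataclass(frozen=True)
class GCResult:
    """Estimated genomic-inflation factor for one trait."""

    lambda_gc: float
    n_intergenic_used: int
    trait: str = "trait"


def intergenic_mask(stats: SumStatsTable, genes=None, flank_bp: int = 0) -> np.ndarray:
    """Boolean mask of SNPs overlapping no gene interval (with optional flank).

    Uses the table's ``intergenic`` column when present and no gene table is
    given; otherwise intersects positions with ``genes`` (DataFrame with
    columns chrom, start, end in 1-based inclusive coordinates).
    """
    df = stats.df
    if genes is None:
        if "intergenic" in df.columns and df["intergenic"].notna().any():
            return df["intergenic"].astype(bool).to_numpy()
        raise ValueError("no intergenic flag column and no gene intervals supplied")
    genic = np.zeros(len(df), dtype=bool)
    for chrom, g in genes.groupby("chrom"):
        sel = df["chrom"].astype(str) == str(chrom)
        if not sel.any():
            continue
        pos = df.loc[sel, "pos"].to_numpy()
        starts = np.sort(g["start"].to_numpy() - flank_bp)
        ends = g["end"].to_numpy() + flank_bp
        order = np.argsort(g["start"].to_numpy())
        ends_sorted = ends[order]
        # pos is genic iff some interval with start<=pos has end>=pos;
        # suffix-max over ends of intervals starting at or before pos
        cummax_end = np.maximum.accumulate(ends_sorted)
        idx = np.searchsorted(starts, pos, side="right") - 1
        hit = idx >= 0
        hit[hit] = cummax_end[idx[hit]] >= pos[hit]
        genic[np.flatnonzero(sel.to_numpy())[hit]] = True
    return ~genic


def _chisq(df) -> np.ndarray:
    z = df["z"].to_numpy(dtype=float)
    chi2 = np.square(z)
    missing = ~np.isfinite(chi2)
    if missing.any():
        p = df["p"].to_numpy(dtype=float)[missing]
        chi2[missing] = sps.chi2.isf(p, df=1)
    return chi2


def estimate_lambda(stats: SumStatsTable, genes=None, *, flank_bp: int = 0,
                    min_intergenic: int = MIN_INTERGENIC) -> GCResult:
    """Estimate lambda_GC = median(chi2) / 0.4549364 over intergenic SNPs.

    Raises
    ------
    ValueError
        If fewer than ``min_intergenic`` intergenic SNPs carry a usable
        statistic.
    """
    mask = intergenic_mask(stats, genes, flank_bp)
    chi2 = _chisq(stats.df.loc[mask])
    chi2 = chi2[np.isfinite(chi2)]
    if len(chi2) < min_intergenic:
        raise ValueError(
            f"only {len(chi2)} intergenic SNPs with valid statistics "
            f"(minimum {min_intergenic})")
    lam = float(np.median(chi2) / CHI2_1_MEDIAN)
    logger.info("%s: lambda_GC = %.4f from %d intergenic SNPs",
                stats.trait, lam, len(chi2))
    return GCResult(lambda_gc=lam, n_intergenic_used=len(chi2), trait=stats.trait)


def apply_genomic_control(stats: SumStatsTable, gc: GCResult, *,
                          deflate: bool = True) -> SumStatsTable:
    """Rescale z by 1/sqrt(lambda_GC) and recompute two-sided p for every SNP.

    With ``deflate=False`` a lambda below 1 leaves the table unchanged (no
    deflation correction), which is logged.  The p-value ranking is preserved
    either way.
    """
    if gc.lambda_gc < 1.0 and not deflate:
        logger.info("%s: lambda_GC = %.4f < 1; statistics left unchanged",
                    stats.trait, gc.lambda_gc)
        return replace(stats, df=stats.df.copy())
    df = stats.df.copy()
    z = df["z"].to_numpy(dtype=float)
    missing = ~np.isfinite(z)
    if missing.any():
        z[missing] = z_from_p(df["p"].to_numpy(dtype=float)[missing])
    z = z / np.sqrt(gc.lambda_gc)
    df["z"] = z
    df["p"] = p_from_z(z)
    return replace(stats, df=df)
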