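"""Conditional and conjunctional false discovery rates for two-trait GWAS.

The conditional FDR of SNP i for the primary trait given the conditioning
trait is the empirical-Bayes quantity

    cFDR(p1_i | p2_i) = p1_i * #{j : p2_j <= p2_i}
                              / #{j : p1_j <= p1_i and p2_j <= p2_i}

i.e. the expected fraction of primary-trait nulls among SNPs at least as
significant as i in the primary trait within the conditioning stratum
{p2 <= p2_i}.  Both counts include SNP i itself, so the denominator is >= 1
and the estimate finite; values are capped at 1.  The reciprocal direction
swaps the roles of the traits, and the conjunctional FDR — used to declare a
locus shared by both traits — is the per-SNP maximum of the two.

The dominance count #{p1_j <= p1_i and p2_j <= p2_i} is computed exactly in
O(n log n) with a Fenwick (binary indexed) tree over p1 ranks, sweeping SNPs
in order of increasing p2 with ties inserted as a group — no interpolation
grid is involved.

Reporting thresholds default to FDR < 0.01 for conditional discovery and
FDR < 0.05 for conjunctional (shared-locus) discovery; the conditional
threshold is stricter because conditioning on an enriched trait raises the
false-positive potential of single-direction calls.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .sumstats import PairedStats

logger = logging.getLogger(__name__)

CONDITIONAL_FDR_THRESHOLD = 0.01
CONJUNCTIONAL_FDR_THRESHOLD = 0.05

#: Number of conditioning-p quantile bands used by monotonicity enforcement.
DEFAULT_MONOTONE_BANDS = 1000

MIN_SNPS_STABLE = 100


class _Fenwick:
    """Fenwick tree over 1..n supporting point add and prefix-sum query."""

    __slots__ = ("n", "tree")

    def __init__(self, n: int):
        self.n = n
        self.tree = [0] * (n + 1)

    def add(self, i: int) -> None:
        t = self.tree
        while i <= self.n:
            t[i] += 1
            i += i & (-i)

    def prefix(self, i: int) -> int:
        s = 0
        t = self.tree
        while i > 0:
            s += t[i]
            i -= i & (-i)
        return s


def dominance_counts(p_primary: np.ndarray, p_cond: np.ndarray) -> np.ndarray:
    """#{j : p_primary_j <= p_primary_i and p_cond_j <= p_cond_i} for every i.

    Exact O(n log n) sweep: SNPs are processed in increasing p_cond order with
    ties inserted together (<= semantics in both dimensions), and a Fenwick
    tree over compressed p_primary ranks answers the prefix counts.
    """
    p_primary = np.asarray(p_primary, dtype=float)
    p_cond = np.asarray(p_cond, dtype=float)
    n = len(p_primary)
    uniq = np.unique(p_primary)
    ranks = np.searchsorted(uniq, p_primary, side="right")  # 1-based
    order = np.argsort(p_cond, kind="stable")
    out = np.empty(n, dtype=np.int64)
    bit = _Fenwick(len(uniq))
    i = 0
    pc = p_cond[order]
    while i < n:
        j = i
        while j < n and pc[j] == pc[i]:
            j += 1
        for k in order[i:j]:          # insert the whole tie group first
            bit.add(int(ranks[k]))
        for k in order[i:j]:
            out[k] = bit.prefix(int(ranks[k]))
        i = j
    return out


def conditional_fdr(paired: PairedStats, direction: int = 1) -> np.ndarray:
    """Raw per-SNP conditional FDR for one direction.

    ``direction=1`` conditions trait 1 on trait 2 (primary p = p1); 2 is the
    reciprocal.  Values are capped at 1.  With fewer than 100 SNPs the
    empirical estimator is unstable; a warning is logged but values are still
    returned.
    """
    if direction not in (1, 2):
        raise ValueError("direction must be 1 or 2")
    df = paired.df
    if len(df) < MIN_SNPS_STABLE:
        logger.warning("conditional FDR on %d SNPs (<%d): estimator unstable",
                       len(df), MIN_SNPS_STABLE)
    p1 = df["p1"].to_numpy(dtype=float)
    p2 = df["p2"].to_numpy(dtype=float)
    prim, cond = (p1, p2) if direction == 1 else (p2, p1)
    sorted_cond = np.sort(cond)
    n_cond = np.searchsorted(sorted_cond, cond, side="right")
    n_both = dominance_counts(prim, cond)
    return np.minimum(prim * n_cond / n_both, 1.0)


def enforce_monotone(values: np.ndarray, paired: PairedStats, direction: int = 1,
                     n_bands: int = DEFAULT_MONOTONE_BANDS) -> np.ndarray:
    """Make cFDR non-decreasing in the primary p within conditioning-p bands.

    SNPs are grouped into ``n_bands`` quantile bands of the conditioning
    p-value; within each band the adjusted value at SNP i is the minimum raw
    value over band members with primary p >= primary p_i (a cumulative
    minimum from the least significant end).  Already-monotone input is a
    fixed point.
    """
    df = paired.df
    prim = df["p1" if direction == 1 else "p2"].to_numpy(dtype=float)
    cond = df["p2" if direction == 1 else "p1"].to_numpy(dtype=float)
    n = len(prim)
    out = np.asarray(values, dtype=float).copy()
    # quantile band by conditioning-p rank (stable: ties stay adjacent)
    band = (np.argsort(np.argsort(cond, kind="stable"), kind="stable")
            * n_bands) // max(n, 1)
    for b in np.unique(band):
        idx = np.flatnonzero(band == b)
        order = idx[np.argsort(prim[idx], kind="stable")]
        v = out[order][::-1]
        out[order] = np.minimum.accumulate(v)[::-1]
    return out


def conjunctional_fdr(cfdr12: np.ndarray, cfdr21: np.ndarray) -> np.ndarray:
    """Per-SNP conjunctional FDR: the maximum of the two conditional FDRs."""
    cfdr12 = np.asarray(cfdr12, dtype=float)
    cfdr21 = np.asarray(cfdr21, dtype=float)
    if cfdr12.shape != cfdr21.shape:
        raise ValueError("the two directions cover different SNP sets")
    return np.maximum(cfdr12, cfdr21)


def compute_cfdr(paired: PairedStats, monotone: bool = True,
                 n_bands: int = DEFAULT_MONOTONE_BANDS) -> pd.DataFrame:
    """Full per-SNP cFDR table for a paired, GC-corrected, pruned SNP set.

    Returns a DataFrame with columns SNP, CHR, BP, P1, P2, CFDR12, CFDR21,
    CONJFDR.  Band-wise monotonicity enforcement is applied to both
    directions by default before the conjunction.
    """
    c12 = conditional_fdr(paired, 1)
    c21 = conditional_fdr(paired, 2)
    if monotone:
        c12 = enforce_monotone(c12, paired, 1, n_bands)
        c21 = enforce_monotone(c21, paired, 2, n_bands)
    df = paired.df
    return pd.DataFrame({
        "SNP": df["variant_id"].to_numpy(),
        "CHR": df["chrom"].to_numpy(),
        "BP": df["pos"].to_numpy(),
        "P1": df["p1"].to_numpy(dtype=float),
        "P2": df["p2"].to_numpy(dtype=float),
        "CFDR12": c12,
        "CFDR21": c21,
        "CONJFDR": conjunctional_fdr(c12, c21),
    })


def select_loci(records: pd.DataFrame, mode: str = "conjunctional",
                threshold: float | None = None, *, direction: int = 1,
                conditioning_trait: str = "trait2",
                exclude_region: tuple | None = None) -> pd.DataFrame:
    """Select significant SNPs at strict FDR < threshold.

    ``mode`` is "conditional" (default threshold 0.01; ``direction`` picks
    which trait is primary) or "conjunctional" (default threshold 0.05).
    ``exclude_region`` = (chrom, start, end) removes a region (e.g. the
    extended HLA block) before selection.  Output is sorted by FDR ascending;
    an empty selection is allowed.
    """
    if mode not in ("conditional", "conjunctional"):
        raise ValueError(f"mode must be conditional|conjunctional, got {mode!r}")
    if threshold is None:
        threshold = (CONDITIONAL_FDR_THRESHOLD if mode == "conditional"
                     else CONJUNCTIONAL_FDR_THRESHOLD)
    col = ("CFDR12" if direction == 1 else "CFDR21") if mode == "conditional" \
        else "CONJFDR"
    df = records
    if exclude_region is not None:
        chrom, start, end = exclude_region
        mask = ~((df["CHR"].astype(str) == str(chrom))
                 & (df["BP"] >= start) & (df["BP"] <= end))
        df = df.loc[mask]
    sel = df.loc[df[col] < threshold].copy()
    sel["FDR"] = sel[col]
    sel["mode"] = mode
    sel["conditioning_trait"] = conditioning_trait
    sel["threshold"] = threshold
    return sel.sort_values("FDR", kind="stable").reset_index(drop=True)
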