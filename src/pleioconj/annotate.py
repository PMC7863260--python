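"""Locus merging, closest-gene annotation and Manhattan plots.

Significant SNPs are chained into loci by single-linkage: calls on the same
chromosome within the merge window (default 250 kb, mirroring the clumping
window) join the same locus.  Each locus is represented by its index SNP (the
member with the smallest FDR, ties broken by position) and annotated with the
gene(s) it overlaps, or the nearest gene by distance to an interval edge when
intergenic; exact distance ties list all tied genes.

Gene intervals come from BED files (0-based half-open) and are converted to
1-based inclusive coordinates on read.  Strand is ignored for distance.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MERGE_KB = 250.0


def read_genes_bed(path) -> pd.DataFrame:
    """Read gene intervals from BED (0-based half-open -> 1-based inclusive).

    Returns a DataFrame with columns chrom, start, end, name (and strand when
    present).  Unnamed intervals get synthetic names.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise ValueError("BED file needs at least chrom, start, end")
    out = pd.DataFrame({
        "chrom": df[0].astype(str),
        "start": pd.to_numeric(df[1]).astype(np.int64) + 1,
        "end": pd.to_numeric(df[2]).astype(np.int64),
    })
    out["name"] = (df[3].astype(str) if df.shape[1] >= 4
                   else [f"interval_{i}" for i in range(len(df))])
    if df.shape[1] >= 6:
        out["strand"] = df[5].astype(str)
    if (out["start"] > out["end"]).any():
        raise ValueError("BED interval with start > end")
    return out


def merge_into_loci(calls: pd.DataFrame, merge_kb: float = DEFAULT_MERGE_KB
                    ) -> pd.DataFrame:
    """Single-linkage merge of significant calls into loci.

    ``calls`` needs columns SNP, CHR, BP, FDR (and optionally P1, mode,
    conditioning_trait).  Returns one row per locus with the index SNP
    (minimum FDR; ties by position), the member list and the genomic span.
    The merge is order-independent and idempotent.
    """
    if calls.empty:
        return pd.DataFrame(columns=["locus_id", "SNP", "CHR", "BP", "FDR",
                                     "P1", "n_snps", "span_start", "span_end",
                                     "members"])
    win = merge_kb * 1000.0
    rows = []
    lid = 0
    for chrom, grp in calls.groupby("CHR", sort=False):
        grp = grp.sort_values("BP", kind="stable")
        bp = grp["BP"].to_numpy(dtype=np.int64)
        breaks = np.flatnonzero(np.diff(bp) > win)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks + 1, [len(bp)]])
        for s, e in zip(starts, ends):
            mem = grp.iloc[s:e]
            idx = mem.sort_values(["FDR", "BP"], kind="stable").iloc[0]
            lid += 1
            rows.append({
                "locus_id": lid,
                "SNP": idx["SNP"], "CHR": chrom, "BP": int(idx["BP"]),
                "FDR": float(idx["FDR"]),
                "P1": float(idx["P1"]) if "P1" in mem.columns else np.nan,
                "conditioning_trait": idx.get("conditioning_trait", ""),
                "mode": idx.get("mode", ""),
                "n_snps": len(mem),
                "span_start": int(mem["BP"].min()),
                "span_end": int(mem["BP"].max()),
                "members": ",".join(mem["SNP"].astype(str)),
            })
    out = pd.DataFrame(rows).sort_values(["FDR", "CHR", "BP"], kind="stable")
    out["locus_id"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def closest_genes(chrom: str, pos: int, genes: pd.DataFrame
                  ) -> tuple[list[str], float]:
    """Gene(s) overlapping ``pos``, else nearest by edge distance (ties listed).

    Returns (names, distance); distance 0 for overlaps, NaN with names
    ["none"] when the chromosome has no genes.
    """
    g = genes.loc[genes["chrom"].astype(str) == str(chrom)]
    if g.empty:
        return ["none"], float("nan")
    start = g["start"].to_numpy(dtype=np.int64)
    end = g["end"].to_numpy(dtype=np.int64)
    inside = (start <= pos) & (pos <= end)
    if inside.any():
        return sorted(g.loc[inside, "name"].unique().tolist()), 0.0
    dist = np.where(pos < start, start - pos, pos - end).astype(float)
    dmin = dist.min()
    names = sorted(g.loc[dist == dmin, "name"].unique().tolist())
    return names, float(dmin)


def assign_closest_gene(loci: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Annotate each locus' index SNP with its closest gene(s)."""
    loci = loci.copy()
    names, dists = [], []
    for _, row in loci.iterrows():
        nm, d = closest_genes(row["CHR"], int(row["BP"]), genes)
        names.append(";".join(nm))
        dists.append(d)
    loci["closest_gene"] = names
    loci["gene_distance"] = dists
    return loci


def manhattan_series(records: pd.DataFrame, mode: str = "conjunctional",
                     threshold: float | None = None,
                     genes: pd.DataFrame | None = None,
                     out_prefix=None, direction: int = 1) -> pd.DataFrame:
    """Series (and optional figure) for a conditional/conjunctional Manhattan plot.

    x is the cumulative genome coordinate by chromosome, y = -log10(FDR); a
    horizontal line marks the reporting threshold (0.05 conjunctional, 0.01
    conditional by default) and significant SNPs are labelled with their
    closest gene when ``genes`` is given.  The series is returned and, when
    ``out_prefix`` is set, written as TSV alongside SVG/PNG figures.
    """
    from .cfdr import (CONDITIONAL_FDR_THRESHOLD, CONJUNCTIONAL_FDR_THRESHOLD)
    if threshold is None:
        threshold = (CONDITIONAL_FDR_THRESHOLD if mode == "conditional"
                     else CONJUNCTIONAL_FDR_THRESHOLD)
    col = ("CFDR12" if direction == 1 else "CFDR21") if mode == "conditional" \
        else "CONJFDR"

    df = records.copy()
    df["_ck"] = pd.to_numeric(df["CHR"], errors="coerce").fillna(np.inf)
    df = df.sort_values(["_ck", "CHR", "BP"], kind="stable")
    offset = 0
    xs = np.empty(len(df), dtype=float)
    ticks = {}
    for chrom, grp in df.groupby("CHR", sort=False):
        loc = df.index.get_indexer(grp.index)
        xs[loc] = grp["BP"].to_numpy(dtype=float) + offset
        ticks[chrom] = offset + grp["BP"].max() / 2
        offset += grp["BP"].max() + 1
    series = pd.DataFrame({
        "SNP": df["SNP"].to_numpy(), "CHR": df["CHR"].to_numpy(),
        "BP": df["BP"].to_numpy(), "x": xs,
        "neglog10_fdr": -np.log10(df[col].to_numpy(dtype=float)),
        "significant": df[col].to_numpy(dtype=float) < threshold,
    })

    labels = []
    if series["significant"].any() and genes is not None:
        sig = series.loc[series["significant"]]
        for _, row in sig.iterrows():
            nm, _ = closest_genes(row["CHR"], int(row["BP"]), genes)
            labels.append((row["x"], row["neglog10_fdr"], ";".join(nm)))

    if out_prefix is not None:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(8, 3.2))
        for i, (chrom, grp) in enumerate(series.groupby("CHR", sort=False)):
            ax.scatter(grp["x"], grp["neglog10_fdr"], s=4,
                       color=["#44658c", "#8c8c8c"][i % 2], rasterized=False)
        ax.axhline(-np.log10(threshold), color="red", lw=1)
        for x, y, nm in labels:
            ax.annotate(nm, (x, y), fontsize=6, rotation=45,
                        textcoords="offset points", xytext=(0, 3))
        ax.set_xticks(list(ticks.values()))
        ax.set_xticklabels(list(ticks.keys()), fontsize=7)
        ax.set_xlabel("chromosome")
        ax.set_ylabel(r"$-\log_{10}$(" + ("cFDR" if mode == "conditional"
                                          else "conjFDR") + ")")
        fig.tight_layout()
        for ext in ("svg", "png"):
            fig.savefig(f"{out_prefix}_manhattan.{ext}", dpi=120)
        plt.close(fig)
        series.to_csv(f"{out_prefix}_manhattan.tsv", sep="\t", index=False,
                      float_format="%.6g")
    return series
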