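"""Conditional QQ plots and fold-enrichment curves for pleiotropic enrichment.

Polygenic overlap between a primary trait and a conditioning trait shows up
as successive leftward/upward deflection of the primary trait's QQ curve when
restricted to SNP subsets increasingly associated with the conditioning
trait.  Strata are nested: stratum k holds all SNPs with
-log10(p2) >= cutpoint_k, with the first cutpoint 0 so stratum 0 is all SNPs.

Fold enrichment at a -log10(p1) threshold t is the tail proportion of the
stratum divided by the tail proportion of all SNPs:

    fold_k(t) = [#{i in stratum k: -log10(p1_i) >= t} / |stratum k|]
                / [#{i: -log10(p1_i) >= t} / n]

so fold(0) = 1 for every stratum and fold > 1 indicates enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sumstats import PairedStats

logger = logging.getLogger(__name__)

#: Minimum SNPs for emitting a QQ curve / keeping a fold-enrichment point.
MIN_STRATUM_QQ = 10
MIN_TAIL_COUNT = 10


@dataclass(frozen=True)
class StratumSpec:
    """Nested conditioning strata as -log10(p2) cutpoints.

    Default cutpoints (0, 1, 2, 3) give strata p2 <= 1, 0.1, 0.01, 0.001.
    """

    cutpoints: tuple = (0.0, 1.0, 2.0, 3.0)
    labels: tuple = ()

    def __post_init__(self):
        cp = tuple(float(c) for c in self.cutpoints)
        if len(cp) == 0 or any(b <= a for a, b in zip(cp, cp[1:])):
            raise ValueError("cutpoints must be non-empty and strictly increasing")
        if cp[0] != 0.0:
            raise ValueError("first cutpoint must be 0 (all-SNP stratum)")
        object.__setattr__(self, "cutpoints", cp)
        if not self.labels:
            object.__setattr__(
                self, "labels",
                tuple("all SNPs" if c == 0 else f"p2 <= 1e-{c:g}" for c in cp))
        elif len(self.labels) != len(cp):
            raise ValueError("labels must match cutpoints")


@dataclass
class QQCurve:
    """Empirical vs expected -log10(p) quantiles for one stratum."""

    label: str
    expected: np.ndarray   # -log10((i-0.5)/m), decreasing in p-rank
    nominal: np.ndarray    # sorted -log10(p1), aligned with expected
    n: int = 0


@dataclass
class EnrichmentCurve:
    """Fold enrichment over a grid of -log10(p1) thresholds for one stratum."""

    label: str
    thresholds: np.ndarray
    fold: np.ndarray
    stratum_size: int = 0


def stratify(paired: PairedStats, spec: StratumSpec | None = None) -> list[np.ndarray]:
    """Index arrays of the nested conditioning strata.

    Stratum k = positions of SNPs with -log10(p2) >= cutpoints[k]; stratum 0
    contains every SNP.  An empty top stratum is emitted empty with a warning.
    """
    spec = spec or StratumSpec()
    if len(paired.df) == 0:
        raise ValueError("empty paired table")
    neglog_p2 = -np.log10(paired.df["p2"].to_numpy(dtype=float))
    strata = [np.flatnonzero(neglog_p2 >= c) for c in spec.cutpoints]
    if len(strata[-1]) == 0:
        logger.warning("top stratum (cutpoint %g) is empty", spec.cutpoints[-1])
    logger.info("stratum sizes: %s", [len(s) for s in strata])
    return strata


def conditional_qq_curves(paired: PairedStats, spec: StratumSpec | None = None
                          ) -> list[QQCurve]:
    """QQ curve of -log10(p1) per conditioning stratum.

    Expected quantiles use the continuity-corrected plotting positions
    (i - 0.5)/m.  Strata with fewer than 10 SNPs are omitted with a warning.
    A null (identity) reference is implied by expected == nominal.
    """
    spec = spec or StratumSpec()
    p1 = paired.df["p1"].to_numpy(dtype=float)
    curves = []
    for label, idx in zip(spec.labels, stratify(paired, spec)):
        m = len(idx)
        if m < MIN_STRATUM_QQ:
            logger.warning("stratum %r has %d SNPs (<%d); QQ curve omitted",
                           label, m, MIN_STRATUM_QQ)
            continue
        nominal = np.sort(-np.log10(p1[idx]))[::-1]          # most significant first
        expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
        curves.append(QQCurve(label=label, expected=expected, nominal=nominal, n=m))
    return curves


def fold_enrichment_curves(paired: PairedStats, spec: StratumSpec | None = None,
                           grid: np.ndarray | None = None) -> list[EnrichmentCurve]:
    """Fold-enrichment curve per stratum over a grid of -log10(p1) thresholds.

    Points where fewer than 10 SNPs overall exceed the threshold are truncated
    from every curve (the tail-proportion denominator becomes unstable).
    """
    spec = spec or StratumSpec()
    neglog_p1 = -np.log10(paired.df["p1"].to_numpy(dtype=float))
    n_all = len(neglog_p1)
    if grid is None:
        hi = max(1.0, np.floor(neglog_p1.max() * 10) / 10)
        grid = np.round(np.arange(0.0, hi + 1e-9, 0.1), 10)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")

    sorted_all = np.sort(neglog_p1)
    count_all = n_all - np.searchsorted(sorted_all, grid, side="left")
    valid = count_all >= MIN_TAIL_COUNT
    prop_all = count_all[valid] / n_all

    curves = []
    for label, idx in zip(spec.labels, stratify(paired, spec)):
        m = len(idx)
        if m == 0:
            continue
        s = np.sort(neglog_p1[idx])
        count_s = m - np.searchsorted(s, grid[valid], side="left")
        fold = (count_s / m) / prop_all
        curves.append(EnrichmentCurve(label=label, thresholds=grid[valid],
                                      fold=fold, stratum_size=m))
    return curves


def curves_to_frames(qq: list[QQCurve], folds: list[EnrichmentCurve]
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format TSV-ready series for the two diagnostics."""
    qq_df = pd.concat([
        pd.DataFrame({"stratum": c.label, "expected": c.expected,
                      "nominal": c.nominal}) for c in qq],
        ignore_index=True) if qq else pd.DataFrame(
            columns=["stratum", "expected", "nominal"])
    fold_df = pd.concat([
        pd.DataFrame({"stratum": c.label, "neglog10_p1_threshold": c.thresholds,
                      "fold": c.fold}) for c in folds],
        ignore_index=True) if folds else pd.DataFrame(
            columns=["stratum", "neglog10_p1_threshold", "fold"])
    return qq_df, fold_df


def render_enrichment(qq: list[QQCurve], folds: list[EnrichmentCurve],
                      out_prefix, title: str = "") -> list[str]:
    """Render the conditional QQ panel and the fold-enrichment panel.

    Writes ``<out_prefix>_qq.{svg,png}`` and ``<out_prefix>_fold.{svg,png}``
    plus the underlying series as TSV; returns the written paths.  The QQ
    panel includes a dashed identity line for the null hypothesis.
    """
    if not qq and not folds:
        raise ValueError("no curves to render")
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    written = []
    if qq:
        fig, ax = plt.subplots(figsize=(5, 5))
        lim = max(c.expected.max() for c in qq)
        ax.plot([0, lim], [0, lim], "k--", lw=1, label="null")
        for c in qq:
            ax.plot(c.expected, c.nominal, lw=1.2, label=c.label)
        ax.set_xlabel(r"expected $-\log_{10}(p)$")
        ax.set_ylabel(r"nominal $-\log_{10}(p)$")
        ax.set_title(f"Conditional QQ {title}".strip())
        ax.legend(fontsize=8)
        for ext in ("svg", "png"):
            path = f"{out_prefix}_qq.{ext}"
            fig.savefig(path, dpi=120)
            written.append(path)
        plt.close(fig)
    if folds:
        fig, ax = plt.subplots(figsize=(5, 4))
        for c in folds:
            ax.plot(c.thresholds, c.fold, lw=1.2, label=c.label)
        ax.axhline(1.0, color="k", ls="--", lw=1)
        ax.set_xlabel(r"$-\log_{10}(p_1)$ threshold")
        ax.set_ylabel("fold enrichment")
        ax.set_yscale("log")
        ax.set_title(f"Fold enrichment {title}".strip())
        ax.legend(fontsize=8)
        for ext in ("svg", "png"):
            path = f"{out_prefix}_fold.{ext}"
            fig.savefig(path, dpi=120)
            written.append(path)
        plt.close(fig)

    qq_df, fold_df = curves_to_frames(qq, folds)
    for name, df in (("qq", qq_df), ("fold", fold_df)):
        if len(df):
            path = f"{out_prefix}_{name}.tsv"
            df.to_csv(path, sep="\t", index=False, float_format="%.6g")
            written.append(path)
    return written
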