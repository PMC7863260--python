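"""Pairwise LD (r-squared) computation and greedy clumping of paired SNPs.

Retained SNPs after clumping are quasi-independent: the most significant SNP
in a region is kept as the index SNP and every unretained neighbour within
the window whose squared correlation with it exceeds the threshold is
removed.  The defaults (r2 > 0.2 within 250 kb) follow plink --clump-style
pruning against a reference-panel LD structure.

LD can be supplied either as a precomputed pairwise table (PLINK .ld-style,
columns SNP_A SNP_B R2) or computed from a small genotype dosage panel.
SNP pairs absent from the table are treated as unlinked (r2 = 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .sumstats import PairedStats

logger = logging.getLogger(__name__)


@dataclass
class LDPairTable:
    """Sparse symmetric store of pairwise r2 values.

    ``pairs`` maps an unordered variant-ID pair (stored sorted) to r2.
    ``window_kb`` records the span the table was computed over, if known.
    """

    pairs: dict = field(default_factory=dict)
    window_kb: float | None = None

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0:
            raise ValueError(f"r2 out of [0,1]: {r2}")
        self.pairs[self._key(a, b)] = float(r2)

    def get(self, a: str, b: str, default: float = 0.0) -> float:
        return self.pairs.get(self._key(a, b), default)

    def __len__(self) -> int:
        return len(self.pairs)

    def neighbours(self) -> dict:
        """Adjacency map variant -> {other: r2} for fast clumping."""
        adj: dict[str, dict[str, float]] = {}
        for (a, b), r2 in self.pairs.items():
            adj.setdefault(a, {})[b] = r2
            adj.setdefault(b, {})[a] = r2
        return adj

    @classmethod
    def from_plink_table(cls, path, window_kb: float | None = None) -> "LDPairTable":
        """Read a whitespace table with headers SNP_A, SNP_B, R2 (extra columns ignored)."""
        df = pd.read_csv(path, sep=r"\s+")
        for col in ("SNP_A", "SNP_B", "R2"):
            if col not in df.columns:
                raise ValueError(f"LD table missing column {col!r}")
        tab = cls(window_kb=window_kb)
        for a, b, r2 in zip(df["SNP_A"], df["SNP_B"], df["R2"]):
            tab.set(str(a), str(b), float(r2))
        return tab

    def to_frame(self) -> pd.DataFrame:
        rows = [(a, b, r2) for (a, b), r2 in self.pairs.items()]
        return pd.DataFrame(rows, columns=["SNP_A", "SNP_B", "R2"])


@dataclass
class GenotypePanel:
    """Small reference panel of dosages in {0,1,2} (NaN = missing).

    ``variants``: DataFrame with variant_id, chrom, pos sorted by position
    within chromosome.  ``dosages``: array of shape (n_variants, n_samples).
    """

    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2 or self.dosages.shape[0] != len(self.variants):
            raise ValueError("dosages must be (n_variants, n_samples)")
        if self.dosages.shape[1] < 2:
            raise ValueError("panel needs at least 2 samples")

    @classmethod
    def from_tsv(cls, path) -> "GenotypePanel":
        """Read a dosage matrix TSV: variant_id, chrom, pos, then one column per sample."""
        df = pd.read_csv(path, sep="\t")
        meta = df[["variant_id", "chrom", "pos"]].copy()
        dos = df.drop(columns=["variant_id", "chrom", "pos"]).to_numpy(dtype=float)
        return cls(variants=meta, dosages=dos)


def _pair_r2(x: np.ndarray, y: np.ndarray) -> float | None:
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 2:
        return None
    x, y = x[ok], y[ok]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return None
    r = float(np.corrcoef(x, y)[0, 1])
    return min(r * r, 1.0)


def compute_r2_window(panel: GenotypePanel, window_kb: float) -> LDPairTable:
    """Squared Pearson correlation of dosages for every pair within the window.

    Monomorphic variants and pairs with fewer than 2 jointly non-missing
    samples are skipped.
    """
    tab = LDPairTable(window_kb=window_kb)
    win = window_kb * 1000.0
    v = panel.variants.reset_index(drop=True)
    for _, grp in v.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy(dtype=float)
        ids = grp["variant_id"].to_numpy()
        for i in range(len(idx)):
            j = i + 1
            while j < len(idx) and pos[j] - pos[i] <= win:
                r2 = _pair_r2(panel.dosages[idx[i]], panel.dosages[idx[j]])
                if r2 is not None:
                    tab.set(ids[i], ids[j], r2)
                j += 1
    return tab


def clump(paired: PairedStats, ld: LDPairTable, r2_threshold: float = 0.2,
          window_kb: float = 250.0, rank_p: str = "min") -> PairedStats:
    """Greedy LD clumping of the paired SNP set.

    SNPs are visited in order of increasing ranking p-value (ties broken by
    position, then variant ID); each visited SNP that has not been removed is
    retained, and all not-yet-retained SNPs on the same chromosome within
    ``window_kb`` with r2 strictly above ``r2_threshold`` to it are removed.
    ``rank_p`` selects the ranking p per SNP: "trait1", "trait2" or "min"
    (the smaller of the two).  The result is deterministic and independent of
    input row order.
    """
    if rank_p not in ("trait1", "trait2", "min"):
        raise ValueError(f"rank_p must be trait1|trait2|min, got {rank_p!r}")
    df = paired.df
    if len(ld) == 0:
        logger.warning("empty LD table: clumping leaves the input unchanged")
        return paired.copy()

    if rank_p == "trait1":
        rank = df["p1"].to_numpy(dtype=float)
    elif rank_p == "trait2":
        rank = df["p2"].to_numpy(dtype=float)
    else:
        rank = np.minimum(df["p1"].to_numpy(dtype=float), df["p2"].to_numpy(dtype=float))

    order = sorted(range(len(df)),
                   key=lambda i: (rank[i], df["pos"].iat[i], df["variant_id"].iat[i]))
    adj = ld.neighbours()
    pos = df["pos"].to_numpy()
    chrom = df["chrom"].astype(str).to_numpy()
    ids = df["variant_id"].to_numpy()
    loc = {vid: i for i, vid in enumerate(ids)}
    win = window_kb * 1000.0

    removed = np.zeros(len(df), dtype=bool)
    retained = np.zeros(len(df), dtype=bool)
    for i in order:
        if removed[i]:
            continue
        retained[i] = True
        for other, r2 in adj.get(ids[i], {}).items():
            j = loc.get(other)
            if j is None or retained[j] or r2 <= r2_threshold:
                continue
            if chrom[j] == chrom[i] and abs(int(pos[j]) - int(pos[i])) <= win:
                removed[j] = True

    out = df.loc[retained].reset_index(drop=True)
    logger.info("clump: retained %d of %d SNPs (r2>%g within %g kb, rank=%s)",
                retained.sum(), len(df), r2_threshold, window_kb, rank_p)
    log = dict(paired.log)
    log.update({"n_clump_input": len(df), "n_clump_retained": int(retained.sum())})
    return replace(paired, df=out, log=log)
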