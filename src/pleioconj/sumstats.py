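"""Reading, validation, harmonization and writing of GWAS summary statistics.

Summary statistics arrive as whitespace/tab-separated tables with one row per
SNP.  Column names vary between consortia, so a :class:`ColumnMap` translates
input headers to the canonical fields (variant_id, chrom, pos, effect_allele,
other_allele, p, z, n, intergenic).  Tables are validated on read: only
biallelic single-nucleotide variants with a usable p-value or z-score are
kept, and every dropped or adjusted row is counted in the table's log.

Two validated tables are combined into a :class:`PairedStats` by intersecting
variant IDs and aligning alleles, flipping the sign of the second trait's
z-score when its effect allele is the other trait's non-effect allele
(directly or after strand complement).  Strand-ambiguous palindromic SNPs
(A/T, C/G) can be removed because their orientation is undecidable from
alleles alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: Smallest p-value substituted for an input p of exactly zero, so that
#: -log10 transforms stay finite downstream.
P_FLOOR = 1e-300

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = frozenset("ACGT")
_PALINDROMIC = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})

CANONICAL_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "p", "z", "n", "intergenic",
]


@dataclass
class ColumnMap:
    """Mapping from canonical field names to input column headers.

    ``p`` and ``z`` may both be mapped; at least one must be.  ``n`` and
    ``intergenic`` are optional.  ``na_values`` are treated as missing.
    """

    variant_id: str = "SNP"
    chrom: str = "CHR"
    pos: str = "BP"
    effect_allele: str = "A1"
    other_allele: str = "A2"
    p: str | None = "P"
    z: str | None = "Z"
    n: str | None = "N"
    intergenic: str | None = None
    na_values: tuple[str, ...] = ("NA", "NaN", "nan", ".", "")

    def required(self) -> dict[str, str]:
        if self.p is None and self.z is None:
            raise ValueError("ColumnMap must map at least one of p or z")
        req = {
            "variant_id": self.variant_id,
            "chrom": self.chrom,
            "pos": self.pos,
            "effect_allele": self.effect_allele,
            "other_allele": self.other_allele,
        }
        return req

    @classmethod
    def from_dict(cls, d: dict) -> "ColumnMap":
        known = {f for f in cls.__dataclass_fields__}  # noqa: C416
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown ColumnMap keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class SumStatsTable:
    """Validated per-SNP summary statistics for one trait.

    ``df`` has the canonical columns; rows are unique by ``variant_id`` and
    sorted by (chrom, pos).  ``log`` counts rows dropped or adjusted during
    validation.
    """

    df: pd.DataFrame
    trait: str = "trait"
    build: str = "GRCh37"
    log: dict = field(default_factory=dict)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.df)


@dataclass
class PairedStats:
    """Allele-harmonized paired statistics for the shared SNP set of two GWAS.

    ``df`` columns: variant_id, chrom, pos, z1, z2, p1, p2.  The sign of
    ``z2`` refers to the same effect allele as ``z1``.
    """

    df: pd.DataFrame
    trait1: str = "trait1"
    trait2: str = "trait2"
    log: dict = field(default_factory=dict)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.df)

    def copy(self) -> "PairedStats":
        return replace(self, df=self.df.copy())


def _chrom_sort_key(chrom: pd.Series) -> pd.Series:
    """Numeric chromosomes sort numerically, others lexically after them."""
    num = pd.to_numeric(chrom, errors="coerce")
    return num.fillna(np.inf)


def p_from_z(z: np.ndarray) -> np.ndarray:
    """Two-sided p-value 2*Phi(-|z|)."""
    return 2.0 * sps.norm.sf(np.abs(z))


def z_from_p(p: np.ndarray) -> np.ndarray:
    """Unsigned z magnitude Phi^-1(1 - p/2) for a two-sided p."""
    return sps.norm.isf(np.asarray(p, dtype=float) / 2.0)


def read_sumstats(path, colmap: ColumnMap | None = None, *, trait: str = "trait",
                  build: str = "GRCh37") -> SumStatsTable:
    """Read and validate a summary-statistics table.

    Rows failing validation are dropped and counted in the returned table's
    ``log``; p = 0 is clamped to :data:`P_FLOOR`.  When both p and z are
    present but inconsistent (two-sided p vs 2*Phi(-|z|) beyond 1e-6 relative
    tolerance), z wins and p is recomputed.

    Raises
    ------
    ValueError
        If a mapped column is missing from the header, or no rows survive
        validation.
    """
    colmap = colmap or ColumnMap()
    raw = pd.read_csv(path, sep=r"\s+", dtype=str, na_values=list(colmap.na_values),
                      keep_default_na=False, compression="infer")
    mapping = dict(colmap.required())
    for opt in ("p", "z", "n", "intergenic"):
        col = getattr(colmap, opt)
        if col is not None and col in raw.columns:
            mapping[opt] = col
    missing = [c for c in mapping.values() if c not in raw.columns]
    if missing:
        raise ValueError(f"missing mapped column(s) in {path}: {missing}")
    if "p" not in mapping and "z" not in mapping:
        raise ValueError(f"neither p column {colmap.p!r} nor z column {colmap.z!r} "
                         f"found in {path}")

    df = pd.DataFrame({canon: raw[src] for canon, src in mapping.items()})
    n0 = len(df)
    log: dict = {"n_input": n0}

    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    for col in ("p", "z", "n"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "intergenic" in df.columns:
        df["intergenic"] = df["intergenic"].astype(str).str.lower().isin(
            {"1", "true", "t", "yes"})

    for al in ("effect_allele", "other_allele"):
        df[al] = df[al].astype(str).str.upper()
    valid_alleles = (df["effect_allele"].isin(_VALID_ALLELES)
                     & df["other_allele"].isin(_VALID_ALLELES)
                     & (df["effect_allele"] != df["other_allele"]))
    log["n_nonsnp_alleles"] = int((~valid_alleles).sum())

    valid_pos = df["pos"].notna() & (df["pos"] >= 1)

    if "p" in df.columns:
        n_pzero = int((df["p"] == 0).sum())
        if n_pzero:
            logger.info("%s: clamping %d p=0 values to %g", trait, n_pzero, P_FLOOR)
        log["n_p_clamped"] = n_pzero
        df.loc[df["p"] == 0, "p"] = P_FLOOR
        p_ok = df["p"].notna() & (df["p"] > 0) & (df["p"] <= 1)
    else:
        df["p"] = np.nan
        p_ok = pd.Series(False, index=df.index)
    if "z" not in df.columns:
        df["z"] = np.nan
    z_ok = df["z"].notna() & np.isfinite(df["z"])
    has_stat = p_ok | z_ok
    log["n_bad_stat"] = int((~has_stat).sum())

    keep = valid_alleles & valid_pos & has_stat
    log["n_dropped"] = int((~keep).sum())
    df = df.loc[keep].copy()

    # reconcile p and z: z is authoritative when both present but inconsistent
    both = df["p"].notna() & df["z"].notna()
    if both.any():
        implied = p_from_z(df.loc[both, "z"].to_numpy())
        rel = np.abs(df.loc[both, "p"].to_numpy() - implied) / np.maximum(implied, P_FLOOR)
        bad = rel > 1e-6
        log["n_p_recomputed"] = int(bad.sum())
        if bad.any():
            idx = df.index[both][bad]
            df.loc[idx, "p"] = p_from_z(df.loc[idx, "z"].to_numpy())
    only_z = df["p"].isna() & df["z"].notna()
    df.loc[only_z, "p"] = p_from_z(df.loc[only_z, "z"].to_numpy())

    # duplicates: keep the record with the largest n, else the first seen
    if df["variant_id"].duplicated().any():
        n_dup = int(df["variant_id"].duplicated().sum())
        log["n_duplicates_removed"] = n_dup
        logger.info("%s: %d duplicate variant IDs; keeping largest-n record", trait, n_dup)
        if "n" in df.columns and df["n"].notna().any():
            df = (df.sort_values("n", ascending=False, kind="stable")
                    .drop_duplicates("variant_id", keep="first"))
        else:
            df = df.drop_duplicates("variant_id", keep="first")

    if df.empty:
        raise ValueError(f"no valid rows after filtering in {path}")

    df["pos"] = df["pos"].astype(np.int64)
    if "n" in df.columns:
        df["n"] = df["n"].astype(float)
    df = (df.assign(_ck=_chrom_sort_key(df["chrom"]))
            .sort_values(["_ck", "chrom", "pos"], kind="stable")
            .drop(columns="_ck")
            .reset_index(drop=True))
    return SumStatsTable(df=df, trait=trait, build=build, log=log)


def _align_alleles(a1: str, a2: str, b1: str, b2: str) -> int | None:
    """Sign multiplier aligning (b1, b2) onto (a1, a2).

    Returns +1 (same orientation), -1 (swapped; flip z sign), or None when
    the allele pairs cannot be reconciled even after strand complement.
    """
    if (b1, b2) == (a1, a2):
        return 1
    if (b1, b2) == (a2, a1):
        return -1
    cb1, cb2 = _COMPLEMENT.get(b1), _COMPLEMENT.get(b2)
    if (cb1, cb2) == (a1, a2):
        return 1
    if (cb1, cb2) == (a2, a1):
        return -1
    return None


def harmonize_pair(s1: SumStatsTable, s2: SumStatsTable,
                   drop_ambiguous: bool = True) -> PairedStats:
    """Intersect two tables on variant_id and align trait-2 z to trait-1 alleles.

    Strand-ambiguous palindromic SNPs (A/T and C/G) are removed when
    ``drop_ambiguous``; irreconcilable allele pairs are always removed.  All
    removals are counted in the result's ``log``.  Positions and chromosome
    come from ``s1``.

    Raises
    ------
    ValueError
        If the intersection of the two variant sets is empty.
    """
    cols1 = ["variant_id", "chrom", "pos", "effect_allele", "other_allele", "p", "z"]
    m = s1.df[cols1].merge(
        s2.df[["variant_id", "effect_allele", "other_allele", "p", "z"]],
        on="variant_id", suffixes=("_1", "_2"))
    log = {"n_common": len(m)}
    if m.empty:
        raise ValueError("empty intersection of variant IDs")

    if drop_ambiguous:
        pal = [
            (e, o) in _PALINDROMIC
            for e, o in zip(m["effect_allele_1"], m["other_allele_1"])
        ]
        pal = np.asarray(pal)
        log["n_palindromic_removed"] = int(pal.sum())
        m = m.loc[~pal]

    signs = np.array([
        _align_alleles(a1, a2, b1, b2) or 0
        for a1, a2, b1, b2 in zip(m["effect_allele_1"], m["other_allele_1"],
                                  m["effect_allele_2"], m["other_allele_2"])
    ])
    log["n_irreconcilable_removed"] = int((signs == 0).sum())
    m = m.loc[signs != 0]
    signs = signs[signs != 0]
    if m.empty:
        raise ValueError("no harmonizable variants shared between tables")

    z1 = m["z_1"].to_numpy(dtype=float)
    z2 = m["z_2"].to_numpy(dtype=float) * signs
    p1 = m["p_1"].to_numpy(dtype=float)
    p2 = m["p_2"].to_numpy(dtype=float)
    # z may be absent in p-only inputs; fill unsigned magnitude from p
    # (the alignment sign is kept so flips remain visible in the output)
    z1 = np.where(np.isnan(z1), z_from_p(p1), z1)
    z2 = np.where(np.isnan(z2), z_from_p(p2) * signs, z2)

    out = pd.DataFrame({
        "variant_id": m["variant_id"].to_numpy(),
        "chrom": m["chrom"].to_numpy(),
        "pos": m["pos"].to_numpy(),
        "z1": z1, "z2": z2, "p1": p1, "p2": p2,
    })
    out = (out.assign(_ck=_chrom_sort_key(out["chrom"]))
              .sort_values(["_ck", "chrom", "pos"], kind="stable")
              .drop(columns="_ck").reset_index(drop=True))
    log["n_paired"] = len(out)
    logger.info("harmonized %d shared SNPs (%s vs %s)", len(out), s1.trait, s2.trait)
    return PairedStats(df=out, trait1=s1.trait, trait2=s2.trait, log=log)


def write_table(records, path) -> None:
    """Write a result table as TSV with scientific-notation floats.

    Floats are serialized with 15 significant digits in scientific notation so
    a round-trip read reproduces values to better than 1e-12 relative
    tolerance.  Refuses to write an empty table.
    """
    df = records.df if hasattr(records, "df") else records
    if df is None or len(df) == 0:
        raise ValueError("refusing to write an empty table")
    df.to_csv(path, sep="\t", index=False, float_format="%.15e")


def read_table(path) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")
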