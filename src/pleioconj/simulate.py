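"""Synthetic paired-GWAS generator with known pleiotropic architecture.

Per-SNP effects follow a four-component mixture: a SNP is null for both
traits, specific to trait 1 or trait 2, or shared (pleiotropic) with
probabilities (pi00, pi10, pi01, pi11).  Active effects are drawn on the
standardized-genotype scale, beta ~ Normal(0, sigma^2), with correlation
rho_beta between the two traits' effects in the shared component.  Summary
z-scores follow the standard large-sample model

    z_t = sqrt(n_t) * beta_t + eps_t,        eps_t ~ Normal(0, lambda_star)

so an injected inflation lambda_star > 1 mimics residual confounding in the
null distribution.  In LD mode SNPs come in blocks with AR(1) correlation
``ld_rho``: the noise is drawn with that correlation and the signal vector is
smeared by the same block correlation matrix (z ~ N(R sqrt(n) beta,
lambda_star R)), which is what clumping against a reference panel assumes.

The generator also emits a toy genome annotation — a gene every 50 SNPs
spanning 10 SNPs, leaving 80% of SNPs intergenic — and, on request, a
genotype panel realizing the same block-LD structure, so every pipeline stage
(genomic control, clumping, enrichment, cFDR calibration) can be exercised
end to end without any external data.  Everything is reproducible from the
config seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genomic_control import CHI2_1_MEDIAN
from .ld import GenotypePanel
from .sumstats import PairedStats, SumStatsTable, p_from_z

logger = logging.getLogger(__name__)

COMPONENTS = ("null", "trait1", "trait2", "shared")

#: Toy annotation geometry: one gene every GENE_EVERY SNPs covering GENE_SPAN.
GENE_EVERY = 50
GENE_SPAN = 10
SNP_SPACING_BP = 5000
CHROM_START_BP = 10_000


def sigma_for_median_chisq(target_median_chisq: float, n: int) -> float:
    """Effect s.d. such that active-SNP z-scores have the target median chi2.

    For z ~ N(0, 1 + n sigma^2), median(z^2) = 0.4549364 (1 + n sigma^2);
    solving gives sigma.
    """
    v = target_median_chisq / CHI2_1_MEDIAN - 1.0
    if v <= 0:
        raise ValueError("target median chi2 must exceed the null median")
    return float(np.sqrt(v / n))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic paired GWAS.

    Defaults encode the calibration design used throughout: 20,000
    independent SNPs, mixture (0.94, 0.025, 0.025, 0.01), and an effect scale
    giving active SNPs a median chi-square of about 30 at n = 50,000.
    """

    m_snps: int = 20_000
    n1: int = 50_000
    n2: int = 50_000
    pi: tuple = (0.94, 0.025, 0.025, 0.01)     # null, trait1, trait2, shared
    sigma1: float = sigma_for_median_chisq(30.0, 50_000)
    sigma2: float = sigma_for_median_chisq(30.0, 50_000)
    rho_beta: float = 0.5
    ld_block_size: int = 1
    ld_rho: float = 0.0
    inflation: float = 1.0                      # lambda* on the null z-variance
    seed: int = 0

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        if len(pi) != 4 or (pi < 0).any() or abs(pi.sum() - 1.0) > 1e-9:
            raise ValueError("pi must be 4 nonnegative proportions summing to 1")
        if self.m_snps < 1:
            raise ValueError("m_snps must be >= 1")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must be in [0, 1)")
        if not -1.0 <= self.rho_beta <= 1.0:
            raise ValueError("rho_beta must be in [-1, 1]")
        if self.inflation < 1.0:
            raise ValueError("inflation lambda* must be >= 1")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")


@dataclass
class SimResult:
    """Everything one replicate produces: tables, truth and annotations."""

    paired: PairedStats
    truth: pd.DataFrame          # variant_id, label, beta1, beta2
    stats1: SumStatsTable
    stats2: SumStatsTable
    genes: pd.DataFrame          # chrom, start, end, name (1-based inclusive)
    config: SimConfig = field(repr=False, default=None)


def _toy_annotation(m: int) -> tuple[np.ndarray, pd.DataFrame]:
    """Intergenic flags and gene intervals for m SNPs on chromosome 1."""
    pos = CHROM_START_BP + SNP_SPACING_BP * np.arange(m)
    genic = np.zeros(m, dtype=bool)
    rows = []
    g = 0
    for start_snp in range(0, m, GENE_EVERY):
        end_snp = min(start_snp + GENE_SPAN - 1, m - 1)
        genic[start_snp:end_snp + 1] = True
        g += 1
        rows.append({"chrom": "1", "start": int(pos[start_snp]),
                     "end": int(pos[end_snp]), "name": f"GENE{g:04d}"})
    return ~genic, pd.DataFrame(rows)


def _ar1_chol(size: int, rho: float) -> np.ndarray:
    idx = np.arange(size)
    corr = rho ** np.abs(idx[:, None] - idx[None, :])
    return np.linalg.cholesky(corr), corr


def simulate_paired_gwas(config: SimConfig) -> SimResult:
    """Draw one replicate of paired summary statistics under the mixture model."""
    rng = np.random.default_rng(config.seed)
    m = config.m_snps
    labels = rng.choice(4, size=m, p=np.asarray(config.pi, dtype=float))

    beta1 = np.zeros(m)
    beta2 = np.zeros(m)
    t1 = labels == 1
    t2 = labels == 2
    sh = labels == 3
    beta1[t1] = rng.normal(0.0, config.sigma1, t1.sum())
    beta2[t2] = rng.normal(0.0, config.sigma2, t2.sum())
    if sh.any():
        # explicit Gaussian construction; robust to sigma = 0 (degenerate cov)
        u1 = rng.standard_normal(sh.sum())
        u2 = rng.standard_normal(sh.sum())
        rho = config.rho_beta
        beta1[sh] = config.sigma1 * u1
        beta2[sh] = config.sigma2 * (rho * u1 + np.sqrt(1.0 - rho * rho) * u2)

    s1 = np.sqrt(config.n1) * beta1
    s2 = np.sqrt(config.n2) * beta2
    sd = np.sqrt(config.inflation)
    if config.ld_block_size <= 1 or config.ld_rho == 0.0:
        z1 = s1 + sd * rng.standard_normal(m)
        z2 = s2 + sd * rng.standard_normal(m)
    else:
        z1 = np.empty(m)
        z2 = np.empty(m)
        B = config.ld_block_size
        chol_cache = {}
        for start in range(0, m, B):
            size = min(B, m - start)
            if size not in chol_cache:
                chol_cache[size] = _ar1_chol(size, config.ld_rho)
            L, R = chol_cache[size]
            sl = slice(start, start + size)
            z1[sl] = R @ s1[sl] + sd * (L @ rng.standard_normal(size))
            z2[sl] = R @ s2[sl] + sd * (L @ rng.standard_normal(size))

    p1 = p_from_z(z1)
    p2 = p_from_z(z2)
    intergenic, genes = _toy_annotation(m)
    pos = CHROM_START_BP + SNP_SPACING_BP * np.arange(m)
    ids = np.array([f"rs{i + 1}" for i in range(m)])

    def _table(z, p, n, trait):
        df = pd.DataFrame({
            "variant_id": ids, "chrom": "1", "pos": pos,
            "effect_allele": "A", "other_allele": "G",
            "p": p, "z": z, "n": float(n), "intergenic": intergenic,
        })
        return SumStatsTable(df=df, trait=trait, build="toy")

    stats1 = _table(z1, p1, config.n1, "trait1")
    stats2 = _table(z2, p2, config.n2, "trait2")
    paired = PairedStats(df=pd.DataFrame({
        "variant_id": ids, "chrom": "1", "pos": pos,
        "z1": z1, "z2": z2, "p1": p1, "p2": p2,
    }))
    truth = pd.DataFrame({
        "variant_id": ids,
        "label": np.array(COMPONENTS)[labels],
        "beta1": beta1, "beta2": beta2,
    })
    return SimResult(paired=paired, truth=truth, stats1=stats1, stats2=stats2,
                     genes=genes, config=config)


def simulate_panel(config: SimConfig, n_samples: int = 200,
                   maf: float = 0.3) -> GenotypePanel:
    """Genotype dosage panel realizing the config's block-LD structure.

    Latent per-sample Gaussians with the AR(1) block correlation are
    thresholded into two independent allele copies at the given minor-allele
    frequency, so dosage correlation within blocks approximates ``ld_rho``
    patterns.  Seeded independently of the summary statistics (seed + 1).
    """
    rng = np.random.default_rng(config.seed + 1)
    m = config.m_snps
    thr = sps.norm.isf(maf)

    def _latent():
        if config.ld_block_size <= 1 or config.ld_rho == 0.0:
            return rng.standard_normal((m, n_samples))
        out = np.empty((m, n_samples))
        B = config.ld_block_size
        chol_cache = {}
        for start in range(0, m, B):
            size = min(B, m - start)
            if size not in chol_cache:
                chol_cache[size] = _ar1_chol(size, config.ld_rho)[0]
            out[start:start + size] = chol_cache[size] @ rng.standard_normal(
                (size, n_samples))
        return out

    dosages = (_latent() > thr).astype(float) + (_latent() > thr).astype(float)
    pos = CHROM_START_BP + SNP_SPACING_BP * np.arange(m)
    variants = pd.DataFrame({
        "variant_id": [f"rs{i + 1}" for i in range(m)],
        "chrom": "1", "pos": pos,
    })
    return GenotypePanel(variants=variants, dosages=dosages)


def evaluate_calls(called_ids, truth: pd.DataFrame, mode: str = "conjunctional",
                   direction: int = 1) -> dict:
    """False-discovery proportion and power of a call set against the truth.

    Conditional mode (trait ``direction`` primary): a true positive has truth
    label of the primary trait's specific component or "shared".
    Conjunctional mode: only "shared" counts.  FDP = FP / max(1, #calls);
    power = TP / #eligible (0 when nothing is eligible).
    """
    called = set(map(str, called_ids))
    unknown = called - set(truth["variant_id"].astype(str))
    if unknown:
        raise ValueError(f"{len(unknown)} called SNPs absent from truth")
    if mode == "conjunctional":
        eligible_labels = {"shared"}
    elif mode == "conditional":
        eligible_labels = {"shared", "trait1" if direction == 1 else "trait2"}
    else:
        raise ValueError(f"unknown mode {mode!r}")
    is_called = truth["variant_id"].astype(str).isin(called).to_numpy()
    is_true = truth["label"].isin(eligible_labels).to_numpy()
    tp = int((is_called & is_true).sum())
    fp = int((is_called & ~is_true).sum())
    n_eligible = int(is_true.sum())
    return {
        "n_calls": len(called), "tp": tp, "fp": fp,
        "fdp": fp / max(1, len(called)),
        "power": tp / n_eligible if n_eligible else 0.0,
        "n_eligible": n_eligible,
    }


def genes_to_bed(genes: pd.DataFrame) -> pd.DataFrame:
    """Convert 1-based inclusive gene intervals to BED-style rows."""
    return pd.DataFrame({
        0: genes["chrom"], 1: genes["start"] - 1, 2: genes["end"],
        3: genes["name"],
    })
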