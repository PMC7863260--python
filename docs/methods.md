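# Methods

## Model and procedure

`pleioconj` maps pleiotropy between two traits from their GWAS summary
statistics alone. The pipeline is: per-trait genomic control → allele
harmonization into a paired table → LD clumping → conditional QQ /
fold-enrichment diagnostics → conditional and conjunctional FDR → locus
merging and gene annotation. Diagnostics and discovery run on the pruned SNP
set, so retained SNPs are approximately exchangeable units.

### Harmonization

Tables are intersected on variant ID; the second trait's z sign is aligned to
the first trait's effect allele, directly or after strand complement.
Palindromic A/T and C/G SNPs are removed by default because their strand is
undecidable from alleles alone. Only biallelic SNPs are kept. When p and z
are both present but disagree beyond 1e−6 relative tolerance, z is taken as
authoritative and p recomputed as 2·Φ(−|z|) — input p-values are commonly
rounded, and dropping such rows would discard usable signal. p = 0 is clamped
to 1e−300 so −log₁₀ transforms stay finite; duplicate IDs keep the record
with the largest sample size (first seen, if none). Every adjustment is
counted in the table's log. No allele-frequency comparison is performed:
frequency columns are often absent from summary statistics, and the z-sign
alignment does not need them.

### Genomic control

λ_GC = median(χ²)/0.4549364 over intergenic SNPs (χ² = z², or the χ²₁
quantile of 1−p when only p is available), with 0.4549364 the median of χ²₁.
A SNP is intergenic when it overlaps no gene interval (configurable flank,
default 0 bp). At least 1,000 intergenic SNPs are required — the sampling
error of a median below that makes the correction worse than none. All
z-scores are divided by √λ and p recomputed, which preserves ranks; both
inflation and deflation are corrected by default, with a `--no-deflate`
switch to skip λ < 1. The correction is idempotent: re-estimating λ on
corrected statistics returns 1 to machine precision.

### LD clumping

Greedy plink-style clumping: visit SNPs by increasing ranking p (ties by
position then ID), retain the current SNP, remove unretained SNPs within
250 kb at r² strictly above 0.2. The ranking p defaults to min(p₁, p₂) —
symmetric in the two traits — and is switchable to either trait. Strict
inequality means r² = 0.2 exactly is kept. Pairs absent from the LD table
are treated as unlinked and the result is independent of input row order.
r² from a dosage panel is the squared Pearson correlation over samples
non-missing in both SNPs; monomorphic SNPs and pairs with fewer than two
joint observations are skipped.

### Enrichment diagnostics

Conditioning strata are nested: stratum k = {−log₁₀(p₂) ≥ cₖ} with default
cutpoints (0, 1, 2, 3), the convention of the cFDR literature; stratum 0 is
all SNPs. QQ curves plot sorted −log₁₀(p₁) against the continuity-corrected
uniform positions −log₁₀((i−0.5)/m); upward deflection of stricter strata
relative to stratum 0 indicates polygenic overlap. Fold enrichment at
threshold t is the stratum tail proportion of −log₁₀(p₁) ≥ t divided by the
all-SNP tail proportion, so fold(0) = 1 by construction. Curves are
truncated where fewer than 10 SNPs overall pass t, and QQ curves are omitted
for strata under 10 SNPs. Note the variance of a fold value is governed by
the *stratum* tail count: points where only a handful of stratum SNPs remain
can swing far from 1 under the null even when the all-SNP tail is dense.

### Conditional and conjunctional FDR

cFDR(p₁ᵢ|p₂ᵢ) = p₁ᵢ · #{j: p₂ⱼ ≤ p₂ᵢ} / #{j: p₁ⱼ ≤ p₁ᵢ ∧ p₂ⱼ ≤ p₂ᵢ}, the
empirical counting estimator computed exactly per SNP: ≤ comparisons
throughout, the index SNP included in both counts (denominator ≥ 1), values
capped at 1. The 2-D dominance counts use a Fenwick-tree sweep in p₂ order
with tie groups inserted before querying — O(n log n), exact, no
interpolation grid and hence no grid-resolution parameter. A monotonicity
step (on by default) makes cFDR non-decreasing in the primary p within each
of 1,000 conditioning-p quantile bands, via the cumulative minimum taken from
the least-significant end of the band. The conjunctional FDR is
max(cFDR₁|₂, cFDR₂|₁).

Reporting thresholds: conditional FDR < 0.01 and conjunctional FDR < 0.05
(strict inequalities), the conditional one stricter because single-direction
calls carry the greater false-positive potential. The conjunction via the
maximum is the field's standard statistic but is not a bound on the
union-null probability (P(null₁ ∪ null₂) ≤ cFDR₁|₂ + cFDR₂|₁, of which the
max is the lower part); in mixtures with strong trait-specific components
the realized false-discovery proportion of conjFDR < 0.05 calls can exceed
0.05 — the replicated calibration study (`analysis/06_fdr_calibration.py`)
measures this directly, and under the default mixture finds the conditional
rule within its nominal rate and the conjunctional rule above it. An
optional region exclusion (e.g. the extended MHC, chr6:25–34 Mb, where LD
violates the exchangeability assumption) is off by default.

### Loci and annotation

Significant SNPs chain into loci by single linkage at 250 kb (mirroring the
clumping window); the index SNP is the member with the smallest FDR, ties
broken by position. The index SNP is annotated with every gene it overlaps,
else the gene(s) at minimal distance to an interval edge, strand ignored;
BED input (0-based half-open) is converted to 1-based inclusive on read.
Manhattan plots place SNPs on a cumulative genome coordinate with
−log₁₀(FDR) on y and a horizontal line at the reporting threshold.

## The simulator

Per SNP a component is drawn from (π₀₀, π₁₀, π₀₁, π₁₁) — null,
trait-1-specific, trait-2-specific, shared. Active effects are
β ~ N(0, σ²) on the standardized-genotype scale, with correlation ρ_β
between the two traits' effects in the shared component; summary z-scores
follow z = √n·β + ε with ε ~ N(0, λ*), λ* ≥ 1 an injected inflation. In LD
mode SNPs form blocks with AR(1) correlation ρ_LD: z ~ N(R√n·β, λ*R), the
standard model of summary statistics under a reference LD structure, and a
matching dosage panel can be drawn by dichotomizing latent Gaussians with the
same block correlation. A toy annotation places one 10-SNP gene every 50
SNPs (20% genic), SNPs 5 kb apart on one chromosome.

Defaults are the calibration design used throughout: m = 20,000 SNPs,
n₁ = n₂ = 50,000, π = (0.94, 0.025, 0.025, 0.01), σ chosen so active SNPs
have median χ² ≈ 30 (σ = √((30/0.4549364 − 1)/n) ≈ 0.036), ρ_β = 0.5 —
shared variants in reported cross-trait analyses tend to show moderately
correlated, not identical, effects — independent SNPs and λ* = 1.

What the simulator does not emulate: realistic allele-frequency spectra
(dosages are symmetric with one MAF), sample overlap between the two studies
(a real source of spurious conjunction), component labels correlated with
gene annotation (real trait-associated SNPs are depleted from intergenic
regions, so the toy λ_GC absorbs smeared polygenic signal — visible in the
`analysis/` study, where λ* = 1.1 is estimated as ≈1.65 under dense block
LD), and varying per-SNP sample sizes. Passing tests therefore demonstrate
the estimators' internal correctness and calibration under the stated
mixture, not robustness to those real-data complications. SNP-level truth
scoring is pessimistic under LD — a retained tagging SNP counts as a false
positive even when it flags a real locus — which is why the calibration
studies use independent SNPs and the LD-mode driver also reports locus-level
containment.

## Numerical choices

- Ties: ≤ comparisons in all counting; clump ties broken by (p, position,
  ID); index-SNP ties by position; equidistant gene ties list all genes.
- Seeds: every stochastic routine takes a single integer seed;
  per-replicate seeds are derived affinely and kept below 2³¹.
- Floats are written in scientific notation with 15 significant digits so
  tables round-trip to better than 1e−12 relative error.
- Degenerate inputs: empty intersections, empty selections and empty strata
  are explicit, logged outcomes, not errors, except where an empty result
  makes the downstream quantity undefined (empty paired table, empty write).
- With all p₂ identical, cFDR reduces exactly to the Benjamini–Hochberg-type
  empirical FDR p₁·n/rank(p₁) — used as a closed-form test anchor.

## Known limitations

- The conjunctional max statistic's FDP can exceed its nominal rate under
  strong trait-specific architectures (measured, see above); interpret
  shared-locus lists as candidates for replication, as the field does.
- The cFDR estimator assumes exchangeable, approximately independent SNPs;
  clumping at r² > 0.2 only approximates this.
- Genomic control with a toy annotation over-corrects when true signal is
  dense among "intergenic" SNPs.
- No liftover, no indel support, no effect-size (beta/SE) harmonization
  beyond the z sign, by design.
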