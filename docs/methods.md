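# Methods

## Model and rationale

Two-sample Mendelian randomization (MR) estimates the causal effect θ of
an exposure on an outcome from GWAS summary statistics, using genetic
variants as instrumental variables. For instrument j with per-allele
exposure effect b̂_j (SE σ_xj) and outcome effect ĝ_j (SE σ_yj), the
Wald ratio is r_j = ĝ_j / b̂_j with first-order SE σ_yj / |b̂_j|. Every
estimator here combines these ratios.

Horizontal pleiotropy — a variant affecting the outcome through a path
other than the exposure — violates the exclusion restriction and biases
ratio-based estimators. Under the omnigenic model's core gene
hypothesis, a polygenic trait has a small set of core genes with direct
biological impact and a large periphery acting through regulation. The
working assumptions of this package are (i) instruments with stronger
variant-exposure associations are more likely to act through core genes,
and (ii) peripheral instruments are more likely to carry horizontal
pleiotropy. The sensitivity analysis therefore ranks instruments by a
strength ("coreness") metric, partitions them into K groups, and tracks
how the causal estimate moves as progressively weaker instruments are
added. Stability across the trajectory supports a causal reading;
drift as peripheral groups enter flags pleiotropy. The group-1
(putative core) estimates are the primary output.

## Ranking and partitioning

Four metrics, all computed from the exposure GWAS:

| criterion | formula | needs |
|---|---|---|
| `abs_beta` (default) | \|b̂_j\| | — |
| `per_variant_h2` | f_j (1 − f_j) b̂_j² | effect-allele frequency |
| `significance` | \|b̂_j\| / σ_xj | — |
| `n_normalized_significance` | \|b̂_j\| / (σ_xj √N_j) | per-variant N |

`per_variant_h2` is proportional to the exposure variance explained by
the variant (the 2 f (1 − f) β² constant is irrelevant to ranking and
dropped); it is symmetric under f ↔ 1 − f, so the effect-allele rather
than minor-allele frequency can be used directly.
`n_normalized_significance` differs from `significance` when per-variant
sample sizes vary, as in GWAS meta-analyses.

Instruments are sorted in descending metric order. Exact ties are
ordered by a seeded random shuffle, applied after canonically sorting
records by variant identifier, so the result is reproducible and
independent of input row order. The ranked list is cut into K contiguous
groups whose sizes differ by at most one; when J mod K ≠ 0 the larger
groups come first, so the core end of the ranking is never under-filled.
A helper suggests K ≈ J/7, giving 5–10 instruments per group; sensitivity
analyses across several K are recommended (the CLI accepts a K list).

## Estimators

* **Wald ratio** (single instrument): β = ĝ/b̂, SE = σ_y/|b̂|.
* **IVW**: inverse-variance weighted mean of ratios with first-order
  weights w_j = 1/ratio-SE², equivalent to WLS of ĝ on b̂ through the
  origin with weights 1/σ_yj². Default is a multiplicative
  random-effects model: the fixed-effect SE √(1/Σw) is inflated by
  √(Q/(J−1)) when Cochran's Q exceeds its degrees of freedom; a
  fixed-effect mode is available. A single-instrument call returns the
  Wald ratio.
* **Weighted median**: sort ratios, attach standardized weights s_j,
  form cumulative midpoints p_j = Σ_{i≤j} s_i − s_j/2 and linearly
  interpolate at p = 0.5. Consistent when valid instruments carry ≥ 50%
  of total weight.
* **Weighted mode**: argmax of a Gaussian-kernel density of the ratios
  with point mass ∝ w_j, evaluated on a 512-point grid spanning
  [min(r) − 3h, max(r) + 3h]. Bandwidth follows a modified Silverman
  rule, h = φ · 0.9 · min(weighted SD, weighted MAD/0.6745) · J^(−1/5)
  with φ = 1 by default, floored at 1e−12 (a warning is logged at the
  floor). Exact density ties resolve to the lower mode. Consistent when
  the largest cluster of ratios comes from valid instruments.

Weighted-median and weighted-mode SEs come from a parametric bootstrap:
each ratio is resampled from Normal(r_j, ratio-SE_j) with weights held
fixed, the statistic recomputed (bandwidth and grid included, for the
mode), and the SE taken as the SD of n_boot = 1000 replicates (the
benchmark harness uses 500 or fewer; see below). Confidence intervals
are β ± z₀.₉₇₅·SE throughout, with two-sided normal p-values.

Median and mode require ≥ 3 instruments; inside the orchestration,
smaller groups yield a missing estimate with a recorded reason instead
of aborting, so trajectories with thin tails remain computable.

**Known limitation.** The parametric bootstrap is conservative for the
KDE-mode statistic: in a controlled experiment (100 equal-precision
instruments, all valid), the bootstrap SE exceeds the mode's true
sampling SD by ≈ 36%, while the same bootstrap for the median is nearly
calibrated. Weighted-mode CIs therefore over-cover (~99% at nominal
95%), consistent with the conservatism reported for mode-based MR
estimators in the literature. Treat mode CIs as conservative bounds.

## Instrument-strength diagnostic

Each group carries the mean per-instrument F-statistic,
F̄ = mean((b̂_j/σ_xj)²). Under `significance` ranking, group 1's F̄
provably dominates the overall F̄. Low F̄ (rule of thumb < 10) warns of
weak-instrument bias.

## Harmonization

Exposure and outcome tables are intersected on variant identifier and
the outcome aligned to the exposure's effect allele: swapped alleles
flip the outcome beta and mirror its frequency; strand flips are
resolved by complementing both alleles. Palindromic variants (A/T, C/G)
cannot be strand-resolved by alleles alone: those with exposure minor
allele frequency above 0.42 are excluded as ambiguous; the rest are
oriented by allele-frequency concordance (a strict mode drops all
palindromes). The exposure side supplies the MAF because instruments
are selected in the exposure GWAS. Variants with beta_exposure = 0,
indels, and allele-incompatible pairs are rejected with per-row reasons;
nothing is dropped silently, and harmonized + rejected counts reconcile
with the intersection size. Harmonization is idempotent and invariant to
strand flips of non-palindromic outcome records. Proxy-variant lookup
and LD-aware operations are out of scope (inputs are assumed
pre-clumped).

## Orchestration and reproducibility

One run ranks and partitions once, then fills the (scope × method × k)
grid: group-specific estimates use group k only; cumulative estimates
use groups 1..k. Each estimate's bootstrap seed is a BLAKE2b hash of
(master seed, method, k, scope) reduced to 31 bits, so results are
independent of evaluation order; group 1 and cumulative k = 1 are the
same instrument set and share a seed. The k = K cumulative estimate is
bit-identical to a single all-instrument call made through
`estimate_all_instruments`, which reuses the same derived seed and the
ranked record ordering (float summation order matters at the
bit-equality level). Changing the master seed perturbs bootstrap SEs
and tie-breaks but not IVW point estimates.

## Synthetic data generator

The generator emulates post-clumping two-sample GWAS summary tables with
an explicit core/peripheral architecture. Per variant: effect-allele
frequency f ~ U(0.05, 0.95); true exposure effect b ~ N(0, s²) with
class-specific scale s (defaults: 0.1 for 10 core, 0.02 for 90
peripheral variants, per-allele effects on a unit-variance trait); true
outcome effect θ·b + a. The direct (pleiotropic) effect a is 0 under
`none`; otherwise a = sign(b)·d with d ~ N(μ, τ²) for targeted classes
(peripheral-only by default) — signing relative to the
exposure-increasing allele makes μ ≠ 0 genuinely directional on the
causal-ratio scale, matching how directional pleiotropy manifests when
instruments are oriented to raise the exposure; `balanced` enforces
μ = 0. Observed effects add independent noise with the standard
unit-variance-trait approximation se = 1/√(2 f (1−f) N) in each of two
non-overlapping samples (defaults N = 100 000 each), so per-variant
F ≈ 2 f (1−f) b² N.

Because real candidate instruments are genome-wide significant in the
exposure GWAS by construction, true exposure effects are redrawn until
|b|/se exceeds `min_instrument_z` (default 5.45, i.e. p < 5×10⁻⁸).
Selection conditions on the *true* effect, so exposure estimates remain
unbiased — winner's curse is deliberately not emulated. Also not
emulated: LD between instruments, sample overlap, binary-outcome
liability scaling, and allele-frequency mismatch between studies.
Passing tests therefore demonstrate estimator and pipeline correctness
under idealized two-sample conditions, not robustness to those
real-data features. Variants receive non-palindromic allele pairs unless
`palindrome_fraction` injects palindromes for harmonization testing.

## Benchmark harness and study scenarios

`run_benchmark` repeats simulate → harmonize → rank → estimate and
summarizes the group-1 versus all-instrument estimates per method: bias,
empirical SD, RMSE, 95% CI coverage and rejection rate at α = 0.05, with
Monte-Carlo SEs. It computes exactly those two estimates per method and
replicate (not the full K-grid). Two scenarios, 200 replicates each, are
exercised by the test suite and the acceptance script:

1. **Parameter recovery** — 100 valid instruments, effect sd 0.15
   (mean F̄ ≈ 10³, comparable to real core instrument groups), θ = 0.3,
   K = 10. All methods recover θ within Monte-Carlo error in both
   scopes. The strong-instrument design is deliberate: with first-order
   ratio weights, weak instruments (F ≈ 20–30) produce a measurable
   regression-dilution attenuation (~1.5% of θ at effect sd 0.02) that
   is a property of the weighting, not an implementation defect.
2. **Core robustness** — 10 valid core instruments (sd 0.1) + 90
   peripheral (sd 0.02) carrying directional pleiotropy
   (μ = τ = 0.02), θ = 0, K = 10, `abs_beta` ranking. The all-instrument
   IVW estimate is strongly biased (≈ 0.26) and rejects the true null in
   essentially every replicate, while the group-1 IVW bias is an order
   of magnitude smaller and the group-1 weighted median keeps
   near-nominal type-I error (~4%).

Benchmarks use n_boot = 200 bootstrap replicates per estimate (SE
precision ≈ 5%, ample for coverage/rejection summaries at 200
replicates); single-analysis defaults stay at 1000.

## Numerical choices

* Tie-breaking noise: one uniform draw per record from a generator
  seeded with the ranking seed, attached in canonical variant-id order.
* Weighted-median interpolation clamps at the extreme sorted ratios
  when 0.5 falls outside [p_1, p_J].
* Mode grid: 512 points minimum (config accepts larger powers of two);
  the argmax takes the first (lowest) grid point on exact ties.
* Instrument tables round-trip losslessly (17-significant-digit TSV,
  round-trip float parsing; "NA" encodes missing optional fields).
* All derived seeds are 31-bit, safe for any integer seed source.
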