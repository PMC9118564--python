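# Methods

This note documents the statistical model, the synthetic-data generator, the
numerical choices, and the known limitations of the `braintmap` pipeline.

## Stage 1: per-ROI diagnostic effect estimation

For a contrast pooling case stages *S* against the CN control group, the
design for each ROI is

    trait = β₀ + β₁·1[diagnosis ∈ S] + β₂·age + β₃·sex + β₄·education + ε

fitted by ordinary least squares. All ROIs in a contrast share one design
matrix, so the per-ROI fits are computed in a single solve
(`(XᵀX)⁻¹XᵀY` over the subjects × ROIs trait matrix). The reported statistic
per ROI is the diagnosis coefficient β₁, its standard error
`se = √(σ̂²·[(XᵀX)⁻¹]₁₁)` with `σ̂² = RSS/(n−5)`, `t = β₁/se`, and the
two-sided p value from the t distribution with `n−5` degrees of freedom.

Choices a user should know about:

* **Case pooling is binary, not ordinal.** Each contrast compares CN against
  the pooled case set with a single indicator; stage ordering only constrains
  *which* pools are formed (contiguous in EMCI < LMCI < AD).
* **p values are two-sided.** Significance maps are rendered as unsigned
  −log10(p); the sign of the effect remains available in β₁.
* **Perfect fits.** A residual sum of squares at rounding-error scale
  relative to the response's total sum of squares (≤ 1e−24·TSS) is treated
  as an exact fit: t becomes ±∞ and p is floored. All p values are floored
  at 1e−300 before −log10, which preserves ranking while avoiding
  infinities.
* **ROI significance.** The default criterion is raw p < 0.05; a per-map
  Bonferroni option (α/#ROIs) is exposed. Both are reported with the
  criterion used, since counting "significant ROIs" depends materially on
  this choice.
* **Education enters as continuous years**; sex is coded male=1/female=0
  (any consistent binary coding yields identical inference for β₁).
* Rank-deficient designs are a hard error naming the collinear columns;
  subjects outside the contrast's groups are dropped before fitting.

## Stage 2: spatial correlation and family-wise control

Each gene's expression vector over the left-hemisphere ROIs is correlated
with each contrast's −log10(p) vector using Pearson's r over
pairwise-complete positions (expression atlases have missing ROIs; the map
does not). The p value uses the exact t transform with `n_used − 2` degrees
of freedom. A flag switches the target to `sign(β₁)·(−log10 p)` for a
direction-aware variant; the default follows the unsigned rendering of the
maps.

* **Unusable tests** (fewer than 3 complete pairs, or zero variance in the
  used positions) are excluded and counted, not assigned r = 0 — r is
  undefined there and silent zeros would distort the family.
* **The Bonferroni denominator is the pooled family** of every
  (gene, contrast) test actually performed: with G usable genes and 6
  contrasts and no exclusions, 6·G (60,162 at G = 10,027). A per-contrast
  denominator is available as an option. The family size is always written
  to the run log and the manifest because the correction is meaningless
  without it.
* `p_adjusted = min(1, p·family_size)`; a gene is an intersection finding
  iff it is significant in every contrast present. The intersection is
  partitioned against an annotation gene set (symbols upper-cased on both
  sides, since annotation databases and atlases disagree on case).

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, at
the scale of the study it stands in for:

* **Cohort**: group sizes default to CN 255 / EMCI 296 / LMCI 218 / AD 202
  (971 subjects). Age is truncated-normal per group (e.g. CN 76.35 ± 6.54 y,
  bounds [55, 95]); sex is Bernoulli with per-group male fractions; education
  is truncated-normal with pooled moments 16.13 ± 2.75 y on [6, 20] for all
  groups (the source demographics print one group near 12 y, inconsistent
  with the pooled value printed beside it; per-group overrides are exposed).
  Note truncation shifts the realized education mean to ≈ 15.7 y.
* **Imaging trait** (SUVR-like): per-ROI baseline ~ U(1.0, 1.3); a random
  40% of ROIs are "affected" with relative weights U(0.5, 1.0); the stage
  effect (defaults 0.10 / 0.20 / 0.30 SUVR for EMCI / LMCI / AD, required
  non-decreasing) multiplies that profile; covariate slopes default to
  age +0.005 SUVR/y, sex +0.02, education −0.01 so covariate adjustment is
  exercised rather than vacuous; residual noise is iid N(0, 0.2²).
* **Expression**: 10,027 genes × 180 ROIs, standard-normal per ROI. A
  planted subset (default 12 genes, matching the intersection size the
  method is meant to surface) is built by the standardized mixture
  `ρ·signal + √(1−ρ²)·noise` against the *true* effect profile, with the
  noise component orthogonalized against the signal so the realized
  correlation equals the target ρ exactly (default 0.5, inside the
  0.35–0.65 band reported for real findings). Correlating against the true
  profile rather than an estimated map keeps the ground truth
  sample-independent, so downstream recovery tests the entire pipeline
  including stage-1 estimation error. Entries are then masked missing
  uniformly at random (default 5%, emulating sparsely sampled regions).
* All outputs are pure functions of (config, seed); cohort and expression
  use independent child streams of the seed so either can be regenerated
  alone.

What the generator does **not** emulate — and therefore what passing tests
do not establish about real data:

* **No spatial autocorrelation across ROIs.** Real brain maps are smooth;
  Pearson p values that treat ROIs as independent samples are
  anticonservative there. The generator's ROI-exchangeable null makes the
  stage-2 FWER guarantee valid *in the simulation*; on real data a
  spatial-autocorrelation-preserving null ("spin test") would be needed and
  is deliberately out of scope.
* No site/batch structure, no APOE or other genetic covariates, no
  donor-level structure in expression, no systematically missing regions.

## Test problem sizes

The statistical suites run at sizes chosen to estimate the relevant rates
tightly while keeping the default test run fast: null-uniformity pools
200 replicate cohorts of 120 subjects (36,000 p values; the KS test at
α = 0.01 then has negligible Monte-Carlo width); the FWER simulation uses
100 replicates at 500 genes × 6 contrasts; recovery runs 20 replicates at
the full 971-subject, 10,027-gene scale, where per-seed runtime is under a
second thanks to the shared-design vectorization.

## Numerical details

* Writers emit floats as `%.17g` and readers parse with round-trip float
  precision, so write→read→write is byte-stable and identical config + seed
  reproduce bitwise-identical CSVs (the manifest records the config hash and
  seed).
* Pearson r is clipped to [−1, 1] after the masked-sums computation;
  variance guards use a relative threshold (1e−10·n·Σx²) so exactly
  constant vectors are flagged rather than producing rounding-noise
  correlations.
* The stage-1 permutation check permutes the diagnosis label only, which is
  valid here because the generator draws covariates independently of
  diagnosis.

## Limitations

* Bonferroni over 60k correlated tests is conservative for discovery; the
  intersection-across-contrasts rule further compounds this. That is the
  method being implemented, not a recommendation.
* Missing expression is handled by load-time exclusion (< 3 observed ROIs)
  plus pairwise-complete deletion per (gene, contrast); no imputation is
  attempted, and `n_used` is recorded per test so the varying degrees of
  freedom are visible.
* The right hemisphere is excluded by design; the hemisphere filter is a
  label-prefix operation and assumes `L_`/`R_`-prefixed atlas labels.
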