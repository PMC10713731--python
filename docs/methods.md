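# Methods

## Setting and model

`metabomr` implements two-sample summary-data Mendelian randomization
(MR): genetic variants serve as instruments for a modifiable exposure
(here, circulating small-molecule metabolite levels) so that the causal
effect of the exposure on a disease outcome (ovarian-cancer phenotypes)
can be estimated from two independent GWAS — one for the exposure, one
for the outcome — without individual-level data.

For instrument j, let beta_X_j (SE se_X_j) be the per-SD effect on the
exposure and beta_Y_j (SE se_Y_j) the log-odds effect on the outcome,
both aligned to the same effect allele. The working measurement model is

    beta_X_j ~ N(xi_j, se_X_j^2)
    beta_Y_j ~ N(theta * xi_j + alpha_j, se_Y_j^2)

where xi_j is the true instrument effect, theta the causal log-odds per
SD of exposure, and alpha_j a direct (pleiotropic) path that is zero for
a valid instrument. Estimates are reported as odds ratios exp(theta)
with 95% CIs exp(theta ± q * se), two-sided p-values, and significance
declared at p < 0.05 with no multiplicity correction (a
Benjamini–Hochberg column is emitted for context but never drives the
flag).

## Instrument selection

1. **Genome-wide significance.** Exposure SNPs with p < 5e-8 (strict
   inequality).
2. **LD clumping.** Greedy, best-p-first: each index SNP removes every
   remaining same-chromosome SNP within 250 kb (inclusive) whose r² with
   it is ≥ 0.01. Ties on p break lexicographically by rsID for
   determinism. The r² panel is user-supplied (square or long-format
   text); without one, a distance-only mode removes everything inside
   the window. A pair missing from the panel is an error by default, or
   treated as r² = 1 in the conservative mode. Kept SNPs are returned in
   index order.
3. **Strength.** Per-SNP F = (beta_X/se_X)², summarized by the
   arithmetic mean; a set passes only when mean F is strictly greater
   than 10. Weak sets are reported with a flag, never silently dropped,
   because exclusion would hide the pair from the report without an
   auditable row. F is computed on the post-harmonization set so the
   reported SNP counts and strengths describe the instruments actually
   used.

## Harmonization

Exposure and outcome records are matched by rsID and aligned to the
exposure's effect allele: identical alleles pass through, swapped
alleles negate beta_Y and flip the allele frequency, and alleles that
match only after A<->T/C<->G complement are treated as strand flips
before the same two rules. Palindromic SNPs (A/T, C/G) cannot be
strand-resolved from labels, so orientation falls back to allele
frequency agreement; they are dropped as ambiguous when either
frequency is missing or both alleles are too close to 0.5
(min(eaf, 1-eaf) > 0.42, the common pipeline convention). Indels and
non-ACGT alleles are rejected at read time so the harmonization rules
stay total. Every dropped SNP is logged with a reason, and
|retained| + |dropped| always equals the input count. Harmonization
never changes |beta_Y| or se_Y — only signs and frequencies.

## Estimators

- **Wald ratio** (k = 1): theta = beta_Y/beta_X with the first-order
  delta-method SE se_Y/|beta_X|.
- **IVW** (k ≥ 2): weighted least squares of beta_Y on beta_X through
  the origin with weights 1/se_Y²; fixed-effects SE
  (sum w beta_X²)^(-1/2); the multiplicative random-effects SE
  multiplies it by max(1, sqrt(Q/(k-1))), so random effects never
  report a smaller SE than fixed. An auto mode picks random effects iff
  Cochran's Q has p < 0.05.
- **Maximum likelihood** (k ≥ 2): the bivariate normal model above
  with alpha = 0, profiling the nuisance xi_j(theta) in closed form and
  optimizing theta one-dimensionally (Brent, xtol 1e-10, initialized at
  the IVW estimate). The SE is the inverse square root of the numerical
  curvature of the profile log-likelihood at the optimum, which equals
  the theta-block of the inverted full information. Unlike IVW, this
  estimator models the exposure-side noise, and its bias at finite
  instrument strength is correspondingly smaller.
- **Simple / weighted median** (k ≥ 3): the interpolated median of the
  per-SNP ratios at standardized cumulative weight 0.5, with equal
  weights (simple) or beta_X²/se_Y² (weighted, the inverse variance of
  the first-order ratio). SEs come from a parametric bootstrap (default
  1000 replicates, seeded, bit-reproducible) resampling both betas from
  their reported normals. Consistent while valid instruments carry a
  majority of the weight.
- **MR-Egger** (k ≥ 3): SNPs oriented to beta_X ≥ 0, then weighted
  regression of beta_Y on beta_X with a free intercept, weights 1/se_Y².
  Both SEs carry the multiplicative inflation max(1, sigma_hat) with
  sigma_hat² = Q_egger/(k-2); inference on t(k-2). The intercept is the
  directional-pleiotropy test; the slope is the causal estimate.

**Method gating.** The default (`by_snp_count`) gating reports, per pair:
Wald ratio at k = 1; IVW fixed + random and maximum likelihood at
k = 2; all of the above plus simple median, weighted median and
MR-Egger at k ≥ 3. This matches the method rows conventional reports
actually print at each SNP count. A `ivw_only_below_4` mode instead
confines every pair with k < 4 to the IVW family, for users who want
the stricter "fewer than four SNPs -> IVW only" protocol; the two modes
coincide at k ≥ 4.

## Diagnostics

Cochran's Q around the fixed-effects IVW estimate, on k-1 df, with the
chi-square upper-tail p; random effects are selected only when p < 0.05
(at exactly 0.05 the fixed model is kept). The Egger intercept (above)
populates the pleiotropy column, rendered "/" when k < 3 makes it
non-assessable. Leave-one-out re-estimates the effect with each
instrument removed, always using fixed-effects IVW on the subset (Wald
ratio when one SNP remains) so rows are comparable regardless of the
full-set model choice.

## Synthetic data generator

The generator emulates the two-GWAS setting at its published scale:
exposure sample size 86,507 (a metabolite GWAS cohort), outcome
66,450 (25,509 cases + 40,941 controls), common variants with MAF drawn
uniform on (0.1, 0.5), and SEs from the standard
1/sqrt(2*maf*(1-maf)*n) approximation for a standardized trait —
applied to both sides to keep the samples symmetric and desk-scale.
Doubling n divides the SEs by sqrt(2) exactly.

True instrument effects are drawn half-normal,
xi_j = |N(0, effect_sd²)| with effect_sd = 0.042, calibrating the mean
F-statistic to ≈ 60 — the upper end of the realistic band for
metabolite mQTLs, which are strong instruments. The half-normal
(oriented to the trait-raising allele, the convention in MR simulation
work) rather than a sign-symmetric normal matters for pleiotropy
scenarios: with symmetric xi a constant directional alpha contributes
E[alpha*xi]/E[xi²] = 0 to the IVW estimand and "directional" pleiotropy
would be indistinguishable from balanced in expectation.

Direct effects alpha_j are zero (`none`), N(0, tau²) (`balanced`), or
N(mu, tau²) (`directional`), applied to a configurable fraction of
instruments (default all) so contamination scenarios like "40% of
instruments carry alpha = +0.1" are expressible. Null SNPs have
xi = alpha = 0. All SNPs sit on one synthetic chromosome at fixed
100 kb spacing (a 250 kb clumping window reaches exactly two neighbors
each side), with alleles drawn from the eight non-palindromic ordered
pairs unless palindromic injection is switched on. Everything is a
deterministic function of (config, seed); sub-stream seeds are derived
by CRC-32 of (base seed, labels) and stay below 2^31.

What the generator does **not** emulate: case-control ascertainment,
realistic LD decay (LD is block-diagonal with constant within-block
r²), allele-frequency spectra, sample overlap between the two GWAS, or
winner's-curse selection on the exposure effects. Passing tests
therefore validate the estimators and pipeline mechanics under the
stated measurement model, not robustness to those additional features
of real data.

## Monte-Carlo validation and observed calibration

The recovery harness scores each estimator's mean bias, RMSE, 95% CI
coverage and rejection rate over seeded replicates. At the reference
conditions (theta = 0.2, k = 100, no pleiotropy, 500 replicates) every
estimator's |mean bias| is below 0.01, and IVW/ML/Egger coverage sits
near 0.95. The median estimators' CIs are conservative by construction:
the parametric bootstrap resamples around the already-noisy observed
betas, double-counting sampling noise, so its SE overestimates the true
sampling SD by ~13–15% here and median coverage lands near 0.98. This
is a property of the prescribed SE method, shared with standard MR
implementations, and is left as-is; the corresponding tight coverage
check in the acceptance suite fails for the simple median and is kept
failing rather than loosened. Under the null (theta = 0, k = 50, 2000
replicates) the IVW test size is within binomial bounds of 0.05. Under
40% directional contamination (alpha = +0.1) the weighted median's mean
bias (~0.2) is several-fold smaller than IVW's (~0.76); note the
weighted median is not unbiased there — its residual bias is of the
order of the valid ratios' spread — it is only markedly more robust.

## Numerical and design choices

- SNP matching is by rsID only (instrument tables are rsID-keyed); no
  position-based rescue, no proxy lookup.
- Clumping windows are per-chromosome, |pos_i - pos_j| ≤ window
  inclusive.
- Rendered report tables print OR/CI at 2 decimals and p-values at 3,
  with "/" for non-assessable diagnostics; exact values always travel
  in a JSON companion file, and the rendered table is never parsed
  back.
- Batch runs derive each pair's seed from (config seed, exposure name,
  outcome name), so results are invariant to manifest order and
  composition; rows are sorted (outcome, exposure, method).
- Wald-ratio p-values use the normal reference; Egger uses t(k-2); the
  profile-ML optimizer errors (carrying its last iterate) rather than
  returning a non-converged value; a non-concave profile curvature is
  also an error.
- Replicate counts in the analysis drivers (300) are a narrative-speed
  choice; the acceptance script runs the full-size versions (2000 null
  / 500 recovery / 200 contamination replicates).

## Known limitations

- No MR-PRESSO, mode-based, multivariable or Steiger extensions.
- No LD computation from genotypes; the r² panel must be supplied.
- The weak-instrument flag is advisory; estimates are still reported.
- Binary-outcome SEs use the continuous-trait approximation; absolute
  SE scales in synthetic data are therefore stylized, though all
  estimator properties are invariant to that scale.
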