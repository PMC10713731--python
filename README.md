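# metabomr

Two-sample Mendelian randomization (MR) for summary-level GWAS data,
built for metabolite-exposure / cancer-outcome screens: instrument
selection, allele harmonization, five causal estimators, heterogeneity
and pleiotropy diagnostics, batch reporting, and a synthetic GWAS
generator with known truth so the entire pipeline is testable offline.

## The problem

Circulating small-molecule metabolites (acylcarnitines, amino acids,
biogenic amines, hexose) are candidate biomarkers for ovarian cancer,
but observational associations are confounded. MR sidesteps confounding
by using genetic variants as instruments: a SNP that raises a
metabolite is randomized at conception, so — if it affects the outcome
only through that metabolite — its outcome association scales the
causal effect. With exposure effects beta_X (SE se_X) from a metabolite
GWAS and outcome log-odds beta_Y (SE se_Y) from a cancer GWAS, aligned
to the same effect allele, the package estimates the causal log-odds
theta per SD of exposure:

- Wald ratio (1 SNP): theta = beta_Y / beta_X, SE = se_Y/|beta_X|
- IVW (≥2 SNPs): weighted regression through the origin, weights
  1/se_Y²; fixed or multiplicative random effects
  (SE × max(1, sqrt(Q/(k−1))))
- Maximum likelihood (≥2): bivariate normal measurement model,
  profiled over the true SNP effects
- Simple / weighted median (≥3): interpolated median of ratio
  estimates; robust while valid instruments carry >50% of weight;
  parametric-bootstrap SE
- MR-Egger (≥3): regression with a free intercept; the intercept tests
  directional pleiotropy, inference on t(k−2)

Instruments must pass p < 5e-8, LD clumping (r² < 0.01 within 250 kb,
greedy by p), and a mean F = mean((beta_X/se_X)²) > 10 strength guard.
Cochran's Q (p < 0.05 → random effects), the Egger intercept, and
leave-one-out rows accompany every result. See `docs/methods.md` for
the full model, defaults and limitations.

## Worked example

The `analysis/` scripts are a complete desk-scale study. `01` simulates
a panel of 10 metabolites × 2 ovarian-cancer phenotypes (4 pairs carry
a real effect, the rest are null); `02` runs the full batch:

```sh
python analysis/01_simulate_study.py
python analysis/02_run_mr_batch.py
```

which prints

```
82 result rows over 20 pairs (0 failures)
pairs flagged by a primary method at p < 0.05: [('metabolite_00', 'overall_oc'),
('metabolite_01', 'overall_oc'), ('metabolite_02', 'serous_oc'),
('metabolite_03', 'overall_oc')]
true causal pairs: [('metabolite_00', 'overall_oc'), ('metabolite_01', 'overall_oc'),
('metabolite_02', 'serous_oc'), ('metabolite_03', 'overall_oc')]
recovered 4/4 causal pairs; 0 null pair(s) flagged
```

and writes `results/mr_results.tsv`, which begins

```
outcome     exposure       method       n_snp  or    ci_low  ci_high  pvalue  p_heterogeneity  p_pleiotropy
overall_oc  metabolite_00  wald_ratio   1      0.69  0.63    0.77     0.000   /                /
overall_oc  metabolite_01  ivw_fixed    4      1.27  1.21    1.34     0.000   0.664            /
...
overall_oc  metabolite_01  mr_egger     4      1.27  1.03    1.57     0.039   /                0.988
```

Reading the block: metabolite_00 has a single instrument, so only a
Wald ratio is reported (OR 0.69 — a 31% lower odds of overall ovarian
cancer per SD — with "/" marking diagnostics that need ≥2 or ≥3 SNPs);
metabolite_01 has 4 instruments, so all method families run, agree
(OR ≈ 1.27), show no heterogeneity (Q p = 0.664) and no directional
pleiotropy (Egger intercept p = 0.988). Exact, full-precision values
live in the `mr_results.full.json` companion; the TSV is rounded for
reading. `03_validate_estimators.py` and `04_recovery_properties.py`
reproduce the oracle checks and Monte-Carlo calibration tables in
`results/`.

The same pipeline is scriptable (`mm.run_pair`, `mm.run_batch`) or
drivable from the shell:

```sh
mr simulate --seed 3 --out sim/
mr run --exposure sim/exposure.tsv --outcome sim/outcome.tsv --ld sim/ld.tsv --out out/
mr batch --manifest manifest.tsv --config cfg.yaml --out out/
mr volcano --results out/results.full.json --out volcano.tsv
```

Real GWAS tables in any column dialect are mapped with a `ColumnMap`
(gzip accepted); every dropped SNP at read, clump or harmonization time
is logged with a reason in a JSON audit trail.

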