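# Methods

This note documents the statistical model, the synthetic-data machinery, the
numerical choices, and the limits of what the package's tests demonstrate.

## Outcome and predictors

The outcome is binary fatty liver (any degree of steatosis on liver
ultrasonography vs none); the optional 4-level grade (none/mild/moderate/
severe) is stored but never modelled.  Candidate predictors are sex
(0 female / 1 male), age (years), Tanner pubertal stage (1–5), BMI (kg/m²),
waist circumference (cm), ALT/AST/GGT (U/L), fasting glucose (mg/dL) and
insulin (µU/mL), HOMA-IR, HDL- and LDL-cholesterol and triglycerides
(mg/dL), mean arterial pressure (mm Hg), uric acid (mg/dL) and CRP (mg/L).
Two variables are derived, never measured independently:
`HOMA-IR = insulin·glucose/405` and `MAP = SBP/3 + 2·DBP/3`; the cohort
validator enforces both identities to 1e-9.  Complete data are assumed: a
missing cell is an error, not an NA.

## Collinearity screen

Before multivariable modelling, predictors are screened by Spearman rank
correlation (mid-ranks for ties).  Collinear *clusters* are the connected
components of the graph with edges |rho| > 0.60 — a deliberate
generalization of pairwise flagging, so that ALT–AST (0.81) and ALT–GGT
(0.61) merge into a single liver-enzyme cluster even though AST–GGT falls
below the threshold.  The representative kept per cluster is an explicit
caller input (a clinical-availability priority list), not an automatic
choice, mirroring how such decisions are actually made (age over pubertal
stage, which needs a pediatric endocrinologist; ALT over AST/GGT; HOMA-IR
over insulin).  Glucose never enters multivariable candidate sets alongside
HOMA-IR, being one of its factors.

## Fractional-polynomial selection

Functional forms come from degree-2 fractional polynomials over the
standard power set P = {-2, -1, -0.5, 0, 0.5, 1, 2, 3} (0 = natural log;
a repeated pair (p, p) contributes z^p and z^p·ln z), applied to
`z = (x + shift)/scale`.  Scales are fixed, not estimated; the defaults pin
ALT/100 and HOMA-IR/10 so coefficients are comparable with the published
equations.  The function-selection closed test runs at alpha = 0.05 (the
conventional level; nothing in the source material states another): FP2 vs
omitted on 4 df, then FP2 vs linear on 3 df, then FP2 vs best FP1 on 2 df,
with chi-square reference distributions; best FP1/FP2 are exhaustive minima
over the 8 powers / 36 pairs.  Binary predictors bypass the FP family and
are tested linear-vs-omitted on 1 df.  Multivariable selection cycles the
closed test over candidates — visited in order of increasing p-value in the
initial all-linear model — each test adjusting for the others' current
forms, until a full cycle changes nothing (flagged unstable after 5 cycles).

Bootstrap inclusion fractions repeat the full cycle on B nonparametric row
resamples (size n, with replacement).  BIF-1 is the percentage of
*converged* resamples retaining the variable in any form, BIF-2 the
percentage retaining a second FP term; modal exponents break ties toward
the lowest power.  A variable with BIF-1 ≥ 66% enters the final model.
Whether the original analysis cycled predictors jointly within each
resample or screened them one at a time is not documented; joint cycling is
implemented here.  Final coefficients are full-data MLEs with percentile
bootstrap 95% CIs (form held fixed across resamples).

### Logistic solver

Fits use a hand-written Newton/IRLS solver (gradient tolerance 1e-8, step
halving, weight floor 1e-12).  Perfect separation is reported as an
explicit error (diverging log-odds with vanishing deviance), rank
deficiency as an error naming the dependent columns; statsmodels GLM serves
as an independent cross-check in the tests.  The 8 + 36 candidate fits of
each closed-test scan run as one vectorized batch (lock-step Newton over
the candidate axis) with candidate columns standardized internally — an
affine, deviance-invariant reparametrization that keeps z^3/z^-2 columns
well conditioned; the scan tolerance is 1e-6, which fixes deviances far
beyond the 1e-5 comparisons the tests make.

## Published scoring equations

The two final models ship as immutable JSON model cards: the BMI model
(age, BMI, (ALT/100)^-2, (ALT/100)^-1, HOMA-IR/10, (HOMA-IR/10)^2,
triglycerides, uric acid; intercept -0.533) and the WC model (same terms
with waist circumference replacing BMI; intercept -0.925).  The published
equation appendix is not reproduced in the available text, so the equations
are reconstructed as intercept + sum of printed coefficient × term — the
only reading the coefficient table admits.  Three printed CI bounds of the
WC model are inconsistent with their *** -flagged negative point estimates
(upper bounds that appear to have lost a minus sign); they are stored as
printed and flagged `ci_suspect`, never silently corrected.

## Internal validation

* **Discrimination** — Harrell's c (= AUROC) by the rank-sum identity, ties
  counted one half; percentile bootstrap CI.
* **Fit** — Cox-Snell R² = 1 − exp(2(ll₀ − ll)/n) with its prevalence-bound
  maximum 1 − exp(2 ll₀/n); Nagelkerke is their ratio.  AIC = −2 ll + 2k,
  BIC = −2 ll + k ln n.
* **Calibration** (three levels) — mean: observed event rate (Wilson 95%
  interval) vs average predicted risk (bootstrap CI); weak: slope of a
  logistic refit on logit(pred), and intercept of a logistic fit with
  logit(pred) as fixed offset (slope pinned at 1), CIs by percentile
  bootstrap on 2000 resamples; moderate: a lowess smooth of outcome on
  predicted risk (span 0.75, robustness iterations off — they would treat a
  binary outcome's events as outliers — evaluated on a 100-point equally
  spaced risk grid) with a histogram of the predictions.  For an MLE scored
  on its own training data the apparent slope is exactly 1 and intercept
  exactly 0; the tests verify this identity to 1e-6.

## Riley sample-size criteria

Three minima, requirement = their maximum, each rounded up: (1) expected
shrinkage ≥ S = 0.9: n₁ = p/((S−1) ln(1 − R²_CS/S)); (2) apparent-minus-
adjusted Nagelkerke ≤ 0.05 via the equivalent shrinkage target
S₂ = R²_CS/(R²_CS + 0.05·max R²_CS); (3) prevalence estimated to ±0.05 with
z = 1.96: n₃ = (1.96/0.05)²·φ(1−φ).  With 20 candidate parameters (the
5-level pubertal stage counts 4 indicators), anticipated R²_CS = 0.11 and
φ = 0.38, the shrinkage criterion binds at n = 1535.

## Synthetic cohort generator

The generator emulates the development cohort (n = 1672, 41.4% boys,
published pubertal-stage frequencies) from exactly what is public:

* **Marginals.**  Each continuous variable's quantile function is
  log-linear in the normal score through its three published quartiles —
  slope (ln p50 − ln p25)/0.6745 below the median, (ln p75 − ln p50)/0.6745
  above, extended linearly into the tails (a two-slope log-normal).  Age is
  clipped to the study range 5–18 y.  Blood pressures are recorded to
  5 mm Hg, which is why their printed quartiles tie (SBP 120 (120–130));
  tied anchors are spread by half a resolution step and samples rounded
  back to the grid, reproducing the ties.
* **Dependence.**  A Gaussian copula with latent correlations
  r = 2 sin(π·rho/6) from the published Spearman matrix, repaired to
  positive definite by eigenvalue clipping (the maximum perturbation is
  logged; ~0.03 with the default targets).  Discretizing the sex and stage
  latents attenuates their realized rank correlations by factors measured
  once by large-sample simulation (0.81 binary, 0.92 five-level); the
  default copula divides those two rows by these constants so realized
  correlations land near the published values (age–stage ≈ 0.82).
* **Derived variables.**  HOMA-IR, MAP, total cholesterol (Friedewald
  identity LDL + HDL + TG/5) and weight (BMI·height²) are computed from
  their parents, so e.g. the near-unit insulin–HOMA-IR rank correlation
  (published 0.98) is emergent — glucose's small relative spread does the
  work — and serves as a check of the generator, not an input.  Height has
  no published correlation row; its latent follows 0.65 × the age row plus
  sex 0.30 (package constants chosen for internal consistency).
* **Outcome.**  Fatty liver is Bernoulli at the risk given by the published
  BMI equation (WC selectable; the two are interchangeable in this
  population) applied to the sampled covariates.  Prevalence (~38%),
  discrimination of the generating equation (c ≈ 0.81) and its mean
  predicted risk are therefore emergent properties, and the package's
  acceptance checks treat them as such.  Grades among cases are drawn from
  the published grade frequencies, independently of the risk.

What the generator does **not** emulate: sex-specific marginals (only the
pooled quartiles are targeted; the published sex-specific medians differ,
e.g. ALT 19 vs 30 U/L), measurement rounding of labs, ultrasound grading
error, any longitudinal structure, and any dependence beyond a Gaussian
copula with the published rank correlations.  Consequently, passing tests
show that the *methods* behave correctly on data with the published
low-order structure — not that the models would reproduce on a new clinical
cohort, which is precisely why the original analysis defers external
validation.

## Problem sizes and determinism

All randomness flows through seeded `numpy` generators; cohorts, bootstrap
summaries and pipeline outputs are bit-reproducible given a seed.  The test
suite and drivers run scaled-down bootstraps (B = 15–200 instead of the
published 1000/2000; selection recovery on one cohort; coefficient recovery
on 50 replicates), sizes chosen so the full suite completes in a few
minutes while leaving every qualitative conclusion intact; the pipeline
defaults keep the published B values.

## Known limitations

* The published AIC/BIC (1746/1794 and 1755/1804) cannot be recomputed
  without the real data; they are consistency-checked only through the
  identity BIC − AIC = k(ln n − 2) ≈ 48.8 at k = 9, n = 1672.
* The closed test's selected FP2 powers on moderate samples can land on a
  neighbour of the generating pair (the FP family is nearly collinear);
  recovery of (-2, -1) for ALT is reliable only at n ≳ 20 000.
* The inclusion threshold, 66%, is inherited as-is; no sensitivity analysis
  is implemented.
* On synthetic cohorts the bootstrap inclusion fractions of HOMA-IR and
  triglycerides sit near the 66% threshold instead of clearly above it (the
  published values are 95.1% and 73.9% in the BMI arm): the quadratic
  HOMA-IR terms nearly cancel over the realistic HOMA-IR range, so the
  generator's emergent HOMA-IR signal is weaker than in the real cohort.
  ALT, the arm's anthropometric variable, age and uric acid reproduce the
  published pattern robustly.
* IDF metabolic-syndrome component flags are exposed only as
  user-configurable cutoffs; the consensus thresholds themselves are not
  shipped.
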