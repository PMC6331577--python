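# Methods

This note records the models implemented by `introgress_stock`, the
assumptions and numerical choices behind them, what the synthetic-data
generator does and does not emulate, and the limitations a user should
keep in mind.

## Farmed-ancestry estimation

The membership probability `P_ind` is a supervised maximum-likelihood
admixture proportion: reference allele frequencies for the wild and farmed
source populations are taken as known, and the single parameter
`q ∈ [0, 1]` maximises the binomial likelihood of the individual's
diagnostic genotypes under per-locus mixture frequencies
`q·farmed + (1−q)·wild`. Loci are treated as independent (a SNP-panel
assumption; no linkage map). This deterministic estimator stands in for
Bayesian clustering software traditionally used for the same task: the
downstream analyses only consume the point estimate, and a deterministic
likelihood maximiser is reproducible and directly testable against a grid
oracle. The likelihood is unimodal in `q` (it is concave in the per-locus
mixture frequency, which is affine in `q`), and the bounded scalar search
(tolerance 1e−10, with an explicit endpoint comparison) agrees with a
10,001-point grid to 1e−4 on all test fixtures.

Numerical choices: reference frequencies are truncated to
[1e−4, 1 − 1e−4] before the likelihood so fixed loci cannot contribute
infinite terms; the standard error is curvature-based,
`1/sqrt(observed information)`, and is finite even at the boundary because
the information is strictly positive whenever wild and farmed frequencies
differ. Individuals with every diagnostic locus missing are returned
flagged `unestimable`, never as a silent zero; thresholding on
`n_loci_used` is left to the caller.

Rescaling to proportion farmed ancestry uses
`D = (P_ind − P_W)/(P_D − P_W)` with the reference-sample averages
`P_W = 0.0644`, `P_D = 0.903` as defaults. Because `P_D < 1` and
`P_W > 0`, raw `D` can fall slightly outside [0, 1]; raw values are
reported (and consumed by all statistical models), with an optional clamp
for summaries only.

For synthetic panels the scaling constants are produced by the same
mechanism that defines them in the field: `simulate_panel` estimates
`q̂` for 400 simulated pure-wild and 400 pure-farmed individuals and
stores the two averages as the panel's `P_W`/`P_D`. The boundary bias of
the constrained MLE makes these averages interior (≈ 0.04 and ≈ 0.96 for
the default 48-locus, divergence-0.6 panel), so `D̂` is approximately
unbiased for the generating admixture proportion — the recovery-slope
property (slope within [0.9, 1.1] at n = 500) verifies this. Panels whose
calibrated spread would be uninformative (divergence ≈ 0) keep the default
constants.

## Parentage assignment

A locus is a Mendelian mismatch when the offspring dosage lies outside
the attainable range of transmitted-allele sums; because each parent
contributes 0 or 1 copies the attainable set is a contiguous range, which
makes the check vectorisable and provably equivalent to enumerating the
four transmission combinations (a property test asserts this on random
trios). Loci with any missing call among the trio are skipped and not
counted in `loci_compared`.

Decisions, all reflecting standard practice for this design:

- `max_mismatch = 2` by default: trios with one or two mismatches are the
  level a genotype-re-checking protocol accepts.
- Candidate pairs are all dam × sire combinations of the broodstock used
  in the offspring's brood year ± 1 (scale-based ageing can err by a
  year), regardless of which pairs were actually crossed.
- Equal-minimum ties are reported `ambiguous`, never broken silently —
  resolving them requires re-genotyping, which numeric data cannot do.
- Offspring with > 20% missing nuclear calls are excluded before scoring;
  the fraction is computed over the 81 nuclear loci only.
- mtDNA never enters exclusion; it verifies maternity of an accepted
  assignment (consistent / inconsistent / untestable on jointly non-missing
  mt loci). Single-parent assignment is not attempted.

## Phenotypes

Smolt length is back-calculated with the classical proportional
body–scale relation (no intercept): `L_i = (S_i/S_total)·L_capture`.
Annulus radii are taken as numeric input in any consistent unit; image
analysis is out of scope. Egg size per dam derives from the count of eggs
spanning 25 cm: diameter `= 250 mm / count`, per-egg volume the sphere
`(π/6)d³` converted to ml, and egg number the total spawned volume over
per-egg volume. Only relative effects enter the downstream log-scale
models, so any constant factor in these conversions cancels; the sphere
model is therefore adequate even if a different volumetric convention was
used when the measurements were taken.

## Mixed models

All linear mixed models have one random intercept (brood year or run
year) and are estimated by **maximum likelihood, not REML**, so AIC is
comparable across fixed-effect structures; the AIC parameter count
includes both the random-intercept and the residual variance. Fits go
through `statsmodels` `MixedLM` with an optimizer ladder (lbfgs → cg →
powell). Two degenerate regimes are handled explicitly: a grouping factor
with fewer than two levels degrades to OLS with a warning, and a
boundary variance estimate (`< 1e−8 ×` residual variance, or a
non-converged mixed fit) is refitted by OLS — the exact ML solution at a
zero variance component — and reported with `re_var = 0` while keeping
the variance parameter in `k` for AIC comparability. A fixed-effects-only
variant of every model is available by setting the spec's group to none
(the count models are sometimes described as least-squares regressions;
the mixed model is the default here and the fixed-effects fit the
explicit fallback).

The count response is the natural log of per-pair recaptured-offspring
counts; family tables only contain pairs with ≥ 1 recapture, so the log is
always defined. Pair introgression is the dam–sire average; the
introgression slope is background-specific (wild-born vs hatchery-reared
dam), implemented as two interaction columns.

The smolt-length model uses log back-calculated smolt length as the
**response** with per-sea-age intercepts and an introgression slope (one
description of this model reads as if length were an explanatory
variable; that is treated as a typo — a growth model with length as
response is the only reading under which a percent size effect,
`100·(exp(slope) − 1)`, is defined).

The run-year model `logit(P_ind) = a_i + b_i·H + e_ij` with i.i.d. normal
observation-level `e` is, at the ML optimum, a cell-means fit on the logit
scale with a pooled residual variance — it is computed in closed form, and
a test checks it against the explicit arithmetic. Proportions at 0 or 1
are nudged inward by 1e−6 before the logit. Per-year Wald z-tests of
`b_i = 0` at α = 0.05 flag significant years; years observed for only one
group are reported untestable. Grand group means are the back-transformed
averages of the per-year levels. No multiple-testing correction is applied
across years.

All 95% intervals are Wald: estimate ± 1.96 SE, transformed afterwards to
the factor (`exp`) or percent (`100·(exp−1)`) scale.

## Sea-age model

For each sex, two log-odds contrasts (1SW and 2SW against the 3+
baseline) are linear in individual ancestry `D`, in the within/among-year
decomposition covariate (year-mean `D` minus the grand mean of year
means), and in independent normal year effects on each contrast. The
marginal likelihood integrates the bivariate year effect per year with a
Laplace approximation: the joint mode is found by damped Newton steps
(closed-form 2×2 solves, vectorised across years, gradient tolerance
1e−9), and the Gaussian curvature correction is applied at the mode.
The outer 8-parameter optimisation uses L-BFGS-B with log-scale standard
deviations bounded in [1e−3, 20]; starting values come from the pooled
category log-odds. Setting the year variances to zero reduces the model
exactly to a fixed-effects multinomial logit, which is cross-checked
against an independent library fit to 1e−3; an adaptive Gauss-Hermite
evaluation of the same integral (order 21, mode-centred) validates the
Laplace value to 1e−3 in the large-cluster regime where the approximation
is sharp. With few fish per year the Laplace log-likelihood can deviate
from the exact integral by O(10⁻²) — a known limitation of the method,
irrelevant for the likelihood-ratio use here (both compared models share
the approximation). Support for an ancestry effect is twice the
log-likelihood difference against the model with both slopes pinned to
zero, referred to χ²(2); under the null the test attains its nominal 5%
level in simulation.

## The synthetic-data generator

The generator's defaults are the study conditions the analysis is meant
to recover, and every regression target retains its generating value:

- Panel: 48 diagnostic + 33 neutral nuclear SNPs and 15 mtDNA SNPs;
  wild/farmed separation at diagnostic loci scales with a divergence
  parameter (default 0.6) and vanishes exactly at 0.
- Broodstock: 85 pairs over 7 brood years; 55% of dams and 65% of sires
  hatchery-reared; ancestry Beta-distributed with means 0.113 (wild-born)
  and 0.303 (hatchery-reared) and concentration 10 (only the means are
  empirically constrained; the concentration sets a realistic spread).
- Recapture counts follow the best count model's linear predictor
  (intercept −4.5564, hatchery-dam 0.5560, wild-dam introgression 1.5145,
  hatchery-dam introgression −0.5018, log egg number 0.7069) with a
  brood-year effect (sd 0.25) and residual (sd 0.5) on the log scale,
  rounded and zero-truncated (families are only observed through
  recaptured adults, whose counts range 1–43). The noise levels and the
  dam-size distribution (lognormal, meanlog log 6120 g, sdlog 0.35, with
  1.45 eggs per gram) are derived from three observed constraints: mean
  family size 878/85 ≈ 10.3, the 1–43 range over 85 families, and the
  order of the reported coefficient standard errors at n = 85.
- Egg size is log-linear with factors 0.86 (hatchery dam) and 0.67 (full
  introgression, wild-born dam); egg number is log-linear in dam weight
  with a 0.9 hatchery factor.
- Offspring genotypes segregate Mendelian from parental genotypes; mtDNA
  is maternal. Genotyping error is a symmetric single-allele flip per call
  (default rate 0.002 — re-checking protocols imply a small but nonzero
  rate); dropout (default 0.04, matching a 96% offspring call rate)
  applies to offspring only, since broodstock are re-genotyped to
  completeness.
- Smolt lengths are log-linear in ancestry with percent effects 6.2
  (hatchery-reared) and 5.0 (wild-born) at full introgression, centred so
  group means sit at 232 mm and 152 mm; scale radii are exactly
  proportional to body length per fish (with between-fish variation in the
  proportionality constant), so back-calculation recovers the generating
  smolt length — phenotype tests then isolate model error from
  measurement error.
- Sea-age categories are drawn from the sea-age model's own linear
  predictors (default slopes 0: no ancestry effect on sea age, the
  finding the defaults encode), so its recovery tests are well posed.
- Run-year samples: 20 years × ~70 adults per group, group means 0.092
  and 0.27 placed on the logit scale, with year noise (sd 0.3) and
  individual noise (sd 0.8) — the individual spread is what the
  observation-level random effect of the run-year model absorbs.

All randomness flows from a single top-level seed through named
substreams, so any part of a study can be regenerated independently and
identical configurations are byte-identical.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: linkage between loci and within-panel
ascertainment structure; uncertainty in the reference frequencies
themselves; broodstock reuse across pairs or years; ageing error in
offspring brood years (the ±1-year search window is exercised only
through its candidate sets); non-random recapture of offspring; per-locus
or batch heterogeneity in genotyping error; and any multi-generation
feedback of introgression in the river.

A related caveat within the pipeline: the end-to-end run regresses on
*estimated* ancestry `D̂`, whose measurement error attenuates slopes
(classical errors-in-variables) — with ~48 diagnostic loci the per-fish
standard error of `D̂` is comparable to the between-fish ancestry spread
within a group, so e.g. the growth slope recovered from `D̂` is biased
toward zero relative to the generating value. Parameter-recovery tests
therefore target the models fitted on generating values; the pipeline
report shows both numbers side by side.

## Problem sizes

The test suite and `scripts/acceptance.py` use study-scale but
desk-sized computations: 200 replicates of 85-pair family tables for the
count and egg models, 200 replicates of 500 hatchery-reared adults for
the growth model, a 20-year × 70-per-group run-year sample for the
overdispersed logit model (30 replicates where a mean is reported), and
100 null replicates of 240 fish over 6 birth years for the sea-age
likelihood-ratio calibration.

## Known limitations

- Wald intervals can be poor for variance components and near-boundary
  effects; no profile or bootstrap intervals are provided.
- Parentage is exclusion-based only; no likelihood (LOD) scoring, no
  sibship reconstruction, and no single-parent assignment.
- `D` is reported raw and may fall outside [0, 1]; consumers who need a
  proportion must opt into clamping.
- The sea-age fit returns point estimates and a likelihood-ratio test but
  no standard errors for its parameters.
- The archived-data comparison (`reproduce_reported_delta_aic`) depends on
  an external download and on the archive's column layout; it maps a small
  set of column aliases and fails loudly otherwise.
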