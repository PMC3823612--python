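# Methods

`bmigrowth` models childhood anthropometry (BMI, weight, height from age
1 to 17) with semi-parametric linear mixed models, derives the two
landmark features of the BMI curve — the adiposity peak (AP) in infancy
and the adiposity rebound (AR) in mid-childhood — per individual, and
quantifies how a 32-SNP adult-BMI allelic score shifts trajectories and
landmarks, with two-cohort meta-analysis. This note records the model,
the numerical choices, what the synthetic-cohort generator does and does
not emulate, and known limitations.

## Growth model

For individual *i* at age *t* (years), with centred age *a = t − 8*:

```
y_i(t) = x_i(t)' β + z_i(t)' b_i + e_i(t)
b_i ~ N(0, G),   e_i ~ N(0, σ² R_i(ρ)),   R_i(ρ)[s,t] = ρ^|s−t|
```

The fixed design holds a truncated-power spline in age, time-independent
covariates, and (optionally) a genetic variable crossed with every spline
column. The residuals follow a continuous-time AR(1): correlation decays
as `ρ^Δage` with Δage in years.

**Bases.** BMI and height use `{1, a, a², a³, (t−2)₊³, (t−8)₊³,
(t−12)₊³}` — a piecewise cubic with knots at 2, 8 and 12 years and
continuous first and second derivatives. Weight uses
`{1, a, (t−2)₊², (t−2)₊³−(t−12)₊³, (t−8)₊², (t−8)₊³−(t−12)₊³, (t−12)₊²}`:
linear below 2 y, cubic on [2, 8) and [8, 12), quadratic beyond 12 y.
The degree drop past the last knot is a hard linear constraint — the
`(t−12)₊³` coefficient is minus the sum of the other cubic coefficients —
absorbed into the design columns so the fitter stays an unconstrained
mixed model. Centring is at exactly 8.0 years (a fixed constant, so the
design is reproducible across datasets), and knots are fixed rather than
selected. A separate infancy basis `{1, t, t², t³, (t−1)₊³}` supports the
birth-to-5-years model used for the AP; its single knot at 1 y is the
minimal flexibility that can place a peak inside [0, 2.5] y while staying
estimable from 3–5 observations per child.

**Genetic terms.** The allelic score (or one SNP dosage) enters as an
interaction with *all* basis columns; the score main effect is the
interaction with the constant column. For the BMI basis this is 7 fixed
parameters, and the likelihood-ratio test (LRT) of "no genetic effect on
the trajectory" has 7 degrees of freedom. The per-allele effect at age
*t* is the linear combination of these coefficients with the basis at
*t*; its standard error comes from the delta method on the fixed-effect
covariance.

Sex is handled by stratified fits (separate models per sex, or a pooled
fit when sex differences are not of interest). For formal sex-specificity
tests a pooled model adds a second genetic column — the score times a
male indicator — interacted with the whole spline, and the LRT drops
that block (7 df for the BMI basis).

**Random effects.** Defaults: `{1, a, a², (t−2)₊³}` for BMI/height and
`{1, a, (t−2)₊²}` for weight — individual level, slope and curvature in
the pre-8 window, which lets rebound timing vary by individual while
remaining estimable from a median of 6–9 measures. The set is
configurable; it is a reconstruction, since the source analyses do not
enumerate theirs.

**Residual variance groups.** Measurement sources differ in error:
parental-report values are noisier than clinic ones. The fitter can give
each source level its own residual SD (a ratio to the reference level,
estimated with the other variance parameters). Ignoring this when the
data contain inflated parental noise attenuates ρ̂ severely (≈0.9 → ≈0.5
on the default simulation), because the model reallocates the extra
parental variance into the white-noise component. The mean shift between
sources is separately handled as an ordinary fixed effect.

## Estimation

Variance parameters are estimated by REML (reported fits) or ML (fits
that feed LRTs). Fixed effects **and** σ² are profiled out, so the
optimizer searches only over the Cholesky factor of G/σ² (log-diagonal
parameterisation, which enforces positive semi-definiteness) and a
logit-transformed ρ. Individuals sharing a measurement-age pattern share
their marginal covariance; the likelihood is accumulated per unique
pattern with one small Cholesky and batched triangular solves per
pattern, which makes the cost per evaluation essentially the number of
distinct patterns rather than the number of individuals.

Numerics: design columns are rescaled to unit root-mean-square
internally (truncated cubic terms reach ~3×10³ at age 17) and all
reported quantities are mapped back. The optimizer is L-BFGS-B with
finite-difference gradients; because the profiled objective sits on a
flat variance ridge, the line search can abort on the difference-noise
floor, so the search restarts from the incumbent with a larger step and
declares convergence only when a restart improves the objective by less
than 10⁻³ nats (relative tolerance ~10⁻⁹ on the log-likelihood). Three
random starts guard against local optima by default; `theta_start`
warm-starts nested refits. Downstream stages refuse non-converged fits.

The marginal log-likelihood implementation is checked against a dense
multivariate-normal evaluation on tiny instances (agreement to 10⁻⁶),
and inverse-variance pooling against a weighted-least-squares closed
form (10⁻¹²).

## Milestones

An individual's curve is their fixed-effect prediction (at their
covariates and score) plus their predicted random effects (BLUPs),
materialised as a `scipy.interpolate.PPoly`. Because the curve is
piecewise cubic its derivative is piecewise quadratic, so all stationary
points are closed-form per segment. The AR is the curve minimum strictly
inside [2, 8] y (positive second derivative); the AP the maximum strictly
inside [0, 2.5] y from the infancy model, which includes only children
with more than two BMI measures before age 5. Among several admissible
stationary points the extreme BMI wins, ties to the earliest age. Roots
within 10⁻⁶ y of a window edge are classified `boundary` and never
reported valid — an edge root means the window clipped a monotone trend.
Analytic ages agree with a 10⁻⁵-step grid search within 10⁻⁴ y.

## Outlier screen

Values more than 4 sample SDs (ddof = 1) from their sex × measure ×
age-bin cell mean are recoded to missing, in a single pass with moments
computed on the raw data (no iteration — reproducible and
order-independent). Bins follow the half-open strata 1–1.49, 1.5–2.49, …,
16.5–17.5 y. Cells with fewer than two values, and zero-SD cells, pass
through unflagged (a 4·0 threshold would flag any deviation). Birth
measures are never filtered; they are covariate-adjusted outcomes.

## Associations and meta-analysis

Cross-sectional links (score → birth measures adjusting for gestational
age; score → milestone age/BMI, optionally adjusting for the partner
quantity; milestone → last observed BMI in [15, 17.5] y) are ordinary
least squares on complete cases, with a hard error on rank-deficient
designs. The variance in BMI explained by the score at each age is
computed from residual sums of squares of two nested longitudinal fits,
`R²(b) = 1 − Σ_b r²_full / Σ_b r²_reduced` over 1-year bins centred on
integer ages 1–16, using marginal (fixed-effects-only) residuals — the
score is a fixed effect, so its contribution lives in the marginal mean;
negative Monte-Carlo estimates are floored at zero and logged.

Cohorts are combined by fixed-effect inverse-variance pooling with
Cochran's Q reported (never used to switch to random effects); per-SNP
LRT p-values are combined without weighting by Fisher's method and
judged at the Bonferroni threshold 0.05/32 = 0.0015625 (displayed
0.0016). Allelic-score pooled effects are judged at 0.05.

## Allelic score

The unweighted score sums effect-allele dosages over the 32 packaged
SNPs (range [0, 64]); the sensitivity variant weights by published
per-allele adult-BMI effects (kg/m²). Missing dosages are mean-imputed
per SNP (logged); dosages outside [0, 2] are fatal. Allele labels are
harmonised against the packaged metadata: a swapped pair flips d → 2−d;
a mismatch at a strand-ambiguous A/T or C/G site is an error. Height is
carried in centimetres everywhere and outputs label units explicitly
(published height effects are sometimes quoted in units too ambiguous to
mirror).

## Synthetic cohorts

The generator exists so every stage is testable without access-controlled
cohort data. Per individual it draws a true childhood BMI curve
`μ(t) + (score − E[score])·g(t) + basis(t)'b`, observes it at a
cohort-style visit schedule with CAR(1) noise (ρ = 0.9, σ = 0.55 kg/m²),
and writes the generating curves alongside the records.

Calibration is anchor-based: μ is the least-squares fit of the childhood
basis to published-style age-bin means (≈17.4 at 1 y, minimum ≈15.9 near
5.6 y, ≈22.5 by 17 y); the infancy curve is pinned to a peak at 0.742 y
(8.9 months) at 18.03 (males) / 17.45 (females) kg/m²; SNP frequencies
come from the packaged table; and g(t) is the quadratic in centred age
solving g(1) = 0, g(15) = 0.15 kg/m² per allele, plus a derivative
condition at the population rebound age targeting a rebound-age shift of
−0.0362 y per allele. Because an individual minimum shifts with the
reciprocal of that individual's curvature (a convex function), the mean
shift over random curves exceeds the population-curve linearisation; the
calibration therefore rescales the derivative target against a
fixed-seed Monte-Carlo estimate of the realized mean shift. The same
convexity drifts the *median* individual rebound age ≈0.14 y above the
population-curve minimum — expected behaviour, and the median stays
inside the published 5.3–6.1 y range.

Presets: a dense cohort (15 candidate childhood visits plus 4 infancy
visits; attendance draws give a median of 9 childhood BMI measures;
four visit ages are parental reports with 1.5× residual SD; no ancestry
PCs) and a sparse clinic cohort (8 candidate visits, median ~6, almost
nothing between 3.2 and 5.5 y, five standard-normal PCs with zero
effect). Individuals attend one of a small set of attendance profiles —
this keeps the number of distinct age patterns small, which is also what
makes the blockwise likelihood fast. Height comes from its own latent
curve and weight is derived as BMI × height², so the three measures are
jointly coherent. A 0.2 % record fraction is multiplied by 0.3 or 2.6 to
emulate gross recording errors; these magnitudes are deliberately far
outside the 4SD band so the outlier screen can recognise them (errors at
~3.9 cell SDs would evade a 4SD rule and contaminate the CAR(1)
estimate — a robustness frontier the screen does not claim to cover).
Birth weight/length depend on gestational age and sex with zero score
effect by default.

What the generator does **not** emulate: visit-age jitter between
individuals (ages are shared across attendance profiles), linkage
disequilibrium between SNPs, population-structure confounding, secular
trends, informative missingness, and pubertal-timing biology. Passing
recovery tests on these cohorts therefore demonstrates correctness of
the estimation machinery under the stated model, not robustness to
everything real cohorts contain.

## Problem sizes in the test-suite

Parameter recovery runs 20 replicates of the full pipeline at n = 2,000
individuals per cohort, the scale at which rebound-shift and
effect-at-15 standard errors are a usable fraction of their targets.
Null-calibration studies (LRT uniformity, Fisher/Q uniformity,
family-wise error of the per-SNP screen) use 200 replicates of smaller
single-schedule cohorts (n = 50–80) drawn from the fitted model family,
where the chi-square reference is empirically exact; the family-wise
error assertion is a one-sided binomial compatibility check against the
5 % target, which is the correct comparison for a Monte-Carlo estimate
of a rate. Single-start optimisation is used inside the replicated
studies; the default remains three starts.

## Known limitations

- The CAR(1)–G decomposition sits on a flat likelihood ridge: ρ, σ² and
  the intercept variance are individually less precise than their
  combination. Estimates of ρ carry meaningful Monte-Carlo spread at
  n ≲ 500.
- LRT p-values rely on chi-square asymptotics; at a few hundred
  observations their extreme tail is mildly anti-conservative (the
  classic F-versus-χ² gap). The per-SNP Bonferroni screen inherits this
  at small n.
- Heteroscedasticity is modelled by measurement source only, not by age.
- BLUP-based milestones are shrunken towards the population curve;
  individual milestone SDs are smaller than biological variability, as
  for any mixed-model landmark derivation.
- The infancy model's spline form is a reconstruction; AP results should
  be read as conditional on that form.
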