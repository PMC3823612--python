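# bmigrowth

Spline linear mixed models for childhood growth trajectories (BMI,
weight, height from age 1 to 17), per-individual adiposity peak and
rebound, and the association of a 32-SNP adult-BMI allelic score with
growth — including two-cohort inverse-variance and Fisher p-value
meta-analysis.

The package is aimed at genetic epidemiologists working with
longitudinal birth-cohort anthropometry. Real cohort records of this
kind are access-controlled, so `bmigrowth` ships a calibrated
synthetic-cohort generator that reproduces the statistical structure of
such studies (visit schedules, parental-report measurement error,
continuous-time AR(1) residual correlation, realistic allele
frequencies); every stage of the pipeline is testable end to end against
known ground truth.

## The model

Growth of individual *i*, with centred age *a = t − 8* years:

```
y_i(t) = x_i(t)'β + z_i(t)'b_i + e_i(t)
b_i ~ N(0, G),    e_i ~ N(0, σ²R_i(ρ)),    corr(e_s, e_t) = ρ^|s−t|
```

where x contains a truncated-power spline basis with knots at 2, 8 and
12 years — piecewise cubic with C² continuity for BMI and height;
linear / cubic / cubic / quadratic segments for weight — plus covariates
and, optionally, a genetic variable interacted with every basis column.
The allelic score is the sum of BMI-increasing-allele dosages over 32
established adult-BMI loci (packaged with effect alleles, published
effects and reference frequencies).

From a fitted model, each child's curve (fixed effects + predicted
random effects) is a piecewise cubic whose stationary points are
closed-form: the **adiposity rebound** is the curve minimum in [2, 8] y;
the **adiposity peak** is the maximum in [0, 2.5] y from a separate
birth-to-5-years model. Per-allele effects at any age, likelihood-ratio
tests of the genetic terms, the variance in BMI explained by the score
per year of age, and fixed-effect / Fisher meta-analysis across cohorts
complete the pipeline. Details and numerical choices: `docs/methods.md`.

## Worked example

```python
import bmigrowth as bg

# a dense-schedule cohort of 500 children with known ground truth
cohort = bg.synthetic_data.simulate_cohort(
    bg.synthetic_data.alspac_like(n=500), seed=7)

# QC (4SD sex/age-bin outlier recoding) + allelic score
frame, qc_report = bg.pipeline.prepare_analysis_frame(
    cohort.growth, cohort.panel, cohort.individuals)

# REML fit of the BMI trajectory model with score interactions
fit = bg.pipeline.fit_trajectory_model(frame, measure="bmi",
                                       genetic="allelic_score", seed=0)
beta, se = bg.growth_lmm.effect_at_age(fit, 15.0)
print(f"per-allele BMI effect at 15 y: {beta:.3f} (SE {se:.3f}) kg/m^2")
print(f"CAR(1) rho: {fit.rho:.2f}")

# adiposity rebound per child, and its shift per risk allele
ar = bg.pipeline.milestone_frame(fit, "ar", cohort.score)
shift = bg.association.linear_assoc(ar, "age", "allelic_score")
print(f"rebound age shift: {shift.beta:.4f} y per allele "
      f"(SE {shift.se:.4f}, n={shift.n})")
```

Output from this exact run:

```
per-allele BMI effect at 15 y: 0.207 (SE 0.027) kg/m^2
CAR(1) rho: 0.91
rebound age shift: -0.0431 y per allele (SE 0.0139, n=462)
```

The generating cohort used a per-allele effect reaching 0.15 kg/m² at
15 y, a rebound-age shift of −0.0362 y per allele and ρ = 0.9: at
n = 500 the estimates land within roughly two standard errors of their
targets (at the n = 2,000 scale used by the acceptance checks they
tighten onto them). The rebound rows are the 462 of 500 children whose
fitted curves have a genuine interior minimum between 2 and 8 years.

A command-line interface mirrors the library:

```bash
bmigrowth simulate --preset alspac-like --n 500 --seed 7 --out-dir sim
bmigrowth qc sim/growth.csv --out-dir res
bmigrowth score sim/dosages.csv --out-dir res
bmigrowth fit res/growth_clean.csv res/allelic_score.csv --measure bmi --out-dir res
bmigrowth milestones res/fit_bmi_all.json --kind ar --out-dir res
bmigrowth assoc --analysis ar --milestone-table res/milestones_ar.csv \
    --score-table res/allelic_score.csv --out-dir res
```

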