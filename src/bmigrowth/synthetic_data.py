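"""Synthetic two-cohort growth data with the structure the models assume.

The generator draws, per individual, a true piecewise-cubic BMI curve

    BMI_i(t) = mu(t) + (score_i - E[score]) * g(t) + basis(t) . b_i,

observes it at a cohort-specific visit schedule with CAR(1)-correlated
residual noise, and emits long-format growth records together with the
generating curves (ground truth for parameter-recovery tests).  Height is
simulated from its own latent curve and weight is derived as
BMI x height^2, so the three measures are jointly coherent.

Calibration is anchor-based rather than hard-coded: the population mean
curves are least-squares fits of the model bases to published-style
age-bin means (BMI ~17.4 at 1 y, minimum ~15.7 near 6 y, ~21-23 by
16-17 y; infancy peak near 9 months at ~17.5-18 kg/m^2), effect-allele
frequencies come from the packaged 32-SNP table, and the per-allele
profile g(t) is a quadratic in centred age solved to satisfy g(1) = 0,
g(15) = 0.15 kg/m^2 and a configured adiposity-rebound shift of
-0.0362 y per allele (via the implicit-function slope -g'(t*)/mu''(t*),
numerically refined on the population curve).

Two presets mirror the cohorts' designs: a dense schedule with parental-
report visits (median ~9 measures, extra parental measurement noise, no
ancestry PCs) and a sparse clinic-only schedule (median ~6 measures,
little data between 3 and 5.5 y, 5 ancestry PCs).  Individuals attend a
visit subset drawn from a small set of attendance profiles, which keeps
the number of distinct age patterns small.  A small fraction of values is
multiplied by a gross-error factor to emulate implausible entries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd

from .genotype_score import DosagePanel, load_snp_metadata
from .milestones import find_adiposity_peak, find_adiposity_rebound
from .spline_basis import SplineBasis, bmi_height_basis, infancy_basis

__all__ = [
    "SimulationParams",
    "SyntheticCohort",
    "alspac_like",
    "raine_like",
    "simulate_genotypes",
    "simulate_cohort",
    "simulate_trajectories",
    "simulate_two_cohorts",
    "ground_truth_milestones",
    "childhood_mean_coefficients",
    "infancy_mean_coefficients",
    "calibrate_genetic_profile",
]

log = logging.getLogger(__name__)

# Age-bin mean BMI anchors (years, kg/m^2) for the childhood population
# curve, dense-cohort style: peak aftermath at 1, rebound minimum near
# 5.5-6, steady rise to ~22.5 by 17.
CHILDHOOD_BMI_ANCHORS = (
    (1.18, 17.42), (1.76, 16.82), (2.95, 16.48), (3.77, 16.25),
    (5.05, 16.02), (5.90, 15.71), (7.31, 16.10), (7.74, 16.31),
    (8.71, 17.15), (9.94, 17.67), (10.75, 18.25), (11.82, 19.04),
    (12.97, 19.64), (13.89, 20.31), (15.32, 21.28), (15.72, 21.41),
    (16.83, 22.47),
)

# Infancy anchors as offsets from the sex-specific peak BMI; the peak age
# and the decline towards the childhood curve mirror the published
# milestone summaries (peak near 8.9-9.4 months).
INFANCY_PEAK_AGE = 0.742  # years, ~8.9 months
INFANCY_PEAK_BMI = {"male": 18.03, "female": 17.45}
_INFANCY_OFFSET_ANCHORS = (
    (0.03, -4.15), (0.20, -1.35), (0.45, -0.35), (1.20, -0.10),
    (2.00, -0.60), (3.00, -0.97), (4.50, -1.35),
)

HEIGHT_ANCHORS = (  # years, cm
    (1.0, 75.0), (2.0, 87.0), (3.0, 95.0), (4.0, 102.0), (6.0, 115.0),
    (8.0, 128.0), (10.0, 139.0), (12.0, 150.0), (14.0, 161.0),
    (16.0, 169.0), (17.0, 171.0),
)

ALSPAC_CHILD_VISITS = (1.2, 1.75, 2.5, 3.5, 4.5, 5.9, 7.5, 8.7, 9.9, 10.75,
                       11.8, 13.0, 14.0, 15.3, 16.8)
ALSPAC_INFANCY_VISITS = (0.09, 0.35, 0.62, 0.85)
ALSPAC_PARENTAL_VISITS = (1.75, 2.5, 3.5, 4.5)
RAINE_CHILD_VISITS = (1.15, 2.1, 3.1, 5.9, 8.0, 10.6, 14.1, 17.0)


@lru_cache(maxsize=None)
def childhood_mean_coefficients() -> tuple:
    """Population BMI curve on the childhood basis, fit to the age-bin
    anchors by least squares."""
    basis = bmi_height_basis()
    ages = np.array([a for a, _ in CHILDHOOD_BMI_ANCHORS])
    vals = np.array([v for _, v in CHILDHOOD_BMI_ANCHORS])
    coef, *_ = np.linalg.lstsq(basis.design(ages), vals, rcond=None)
    return tuple(coef)


@lru_cache(maxsize=None)
def infancy_mean_coefficients(sex: str) -> tuple:
    """Infancy BMI curve (birth to 5 y) with a maximum at the target peak.

    Weighted least squares on the offset anchors plus a heavily weighted
    zero-derivative row at the peak age pins the curve maximum.
    """
    basis = infancy_basis()
    peak = INFANCY_PEAK_BMI[sex]
    ages = np.array([a for a, _ in _INFANCY_OFFSET_ANCHORS] + [INFANCY_PEAK_AGE])
    vals = np.array([peak + d for _, d in _INFANCY_OFFSET_ANCHORS] + [peak])
    w = np.ones(len(ages))
    w[-1] = 8.0
    A = basis.design(ages)
    t = INFANCY_PEAK_AGE
    deriv_row = np.array([0.0, 1.0, 2 * t, 3 * t**2, 0.0])  # t < knot at 1 y
    A = np.vstack([A * w[:, None], 60.0 * deriv_row])
    b = np.concatenate([vals * w, [0.0]])
    coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    return tuple(coef)


@lru_cache(maxsize=None)
def height_mean_coefficients() -> tuple:
    basis = bmi_height_basis()
    ages = np.array([a for a, _ in HEIGHT_ANCHORS])
    vals = np.array([v for _, v in HEIGHT_ANCHORS])
    coef, *_ = np.linalg.lstsq(basis.design(ages), vals, rcond=None)
    return tuple(coef)


def _population_ar(mu_coef) -> float:
    curve = bmi_height_basis().curve(np.asarray(mu_coef))
    ms = find_adiposity_rebound(curve)
    if not ms.valid:
        raise RuntimeError("population curve has no adiposity rebound")
    return ms.age


@lru_cache(maxsize=None)
def calibrate_genetic_profile(g15: float, ar_shift: float,
                              re_sd: tuple | None = None,
                              center: float = 8.0,
                              n_mc: int = 400) -> np.ndarray:
    """Per-allele effect profile g(t) = c0 + c1 a + c2 a^2 (a = t - 8).

    Solves g(1) = 0, g(15) = g15 and a derivative condition at the
    population rebound age t* making the per-allele rebound-age shift
    equal ``ar_shift`` (implicit-function slope dt*/dscore =
    -g'(t*)/mu''(t*)).  Because the shift of an individual minimum scales
    with the reciprocal of that individual's curvature, averaging over
    the random-effect distribution (``re_sd`` on the childhood random
    columns) yields a larger mean shift than the population curve alone;
    the derivative target is therefore rescaled against a fixed-seed
    Monte-Carlo estimate of the realized mean shift.  Returns the profile
    embedded in the 7-column childhood basis order.
    """
    mu_coef = np.asarray(childhood_mean_coefficients())
    basis = bmi_height_basis()
    mu_curve = basis.curve(mu_coef)
    t_star = _population_ar(mu_coef)
    mu_pp = float(mu_curve.derivative(2)(t_star))

    def solve(gprime_target):
        a1, a15, astar = 1.0 - center, 15.0 - center, t_star - center
        A = np.array([[1.0, a1, a1**2],
                      [1.0, a15, a15**2],
                      [0.0, 1.0, 2 * astar]])
        c = np.linalg.solve(A, np.array([0.0, g15, gprime_target]))
        out = np.zeros(basis.n_columns)
        out[:3] = c
        return out

    def realized_shift(g_full):
        if re_sd is None:
            delta = 2.0
            ms = find_adiposity_rebound(basis.curve(mu_coef + delta * g_full))
            return (ms.age - t_star) / delta if ms.valid else None
        rng = np.random.default_rng(1234)
        sds = np.asarray(re_sd, dtype=float)
        re_cols = (0, 1, 2, 4)
        delta, shifts = 2.0, []
        for _ in range(n_mc):
            coefs = mu_coef.copy()
            for sd, col in zip(sds, re_cols):
                coefs[col] += rng.normal(0.0, sd)
            lo = find_adiposity_rebound(basis.curve(coefs - delta * g_full))
            hi = find_adiposity_rebound(basis.curve(coefs + delta * g_full))
            if lo.valid and hi.valid:
                shifts.append((hi.age - lo.age) / (2 * delta))
        return float(np.mean(shifts)) if shifts else None

    gprime = -ar_shift * mu_pp
    g_full = solve(gprime)
    if ar_shift != 0.0:
        for _ in range(2):
            realized = realized_shift(g_full)
            if realized is None or realized == 0.0:
                break
            gprime *= ar_shift / realized
            g_full = solve(gprime)
    return g_full


@dataclass(frozen=True)
class SimulationParams:
    """Everything that defines one synthetic cohort.

    Defaults (via the :func:`alspac_like` / :func:`raine_like` presets)
    are the study-like conditions: schedule densities, Table-like BMI
    anchors, a per-allele effect reaching 0.15 kg/m^2 at 15 y, a rebound
    shift of -0.0362 y per allele, CAR(1) rho = 0.9, and 50 % extra
    measurement noise on parental-report visits.
    """

    n: int = 2000
    cohort_id: str = "alspac_like"
    eaf_column: str = "eaf_alspac"
    sex_ratio_male: float = 0.5125
    childhood_schedule: tuple = ALSPAC_CHILD_VISITS
    infancy_schedule: tuple = ALSPAC_INFANCY_VISITS
    parental_visits: tuple = ALSPAC_PARENTAL_VISITS
    attendance: float = 0.62
    infancy_attendance: float = 0.8
    n_attendance_profiles: int = 12
    g15: float = 0.15                      # kg/m^2 per allele at 15 y
    ar_shift_per_allele: float = -0.0362   # years per allele
    ap_effect_slope: float = 0.02          # kg/m^2 per allele per year (infancy)
    re_sd: tuple = (1.1, 0.14, 0.025, 0.0005)   # const, a, a^2, (t-2)+^3
    infancy_re_sd: tuple = (0.55, 0.25, 0.09)   # const, t, t^2
    sigma: float = 0.55                    # kg/m^2 residual SD
    rho: float = 0.9                       # CAR(1) per-year correlation
    infancy_sigma: float = 0.45
    parental_noise_mult: float = 1.5
    implausible_rate: float = 0.002
    n_pcs: int = 0
    height_re_sd: tuple = (4.0, 0.35)
    height_sigma: float = 0.9
    height_g_slope: float = 0.012          # cm per allele per year past 1 y
    birth_effect: float = 0.0              # kg per allele on birth weight
    dosage_jitter: float = 0.0             # beta-like smoothing of dosages


def alspac_like(n: int = 2000, **overrides) -> SimulationParams:
    """Dense-schedule cohort: infancy visits, parental reports, no PCs."""
    return replace(SimulationParams(n=n), **overrides)


def raine_like(n: int = 600, **overrides) -> SimulationParams:
    """Sparse clinic-only cohort with 5 ancestry PCs and no infancy data."""
    base = SimulationParams(
        n=n, cohort_id="raine_like", eaf_column="eaf_raine",
        sex_ratio_male=0.5158,
        childhood_schedule=RAINE_CHILD_VISITS, infancy_schedule=(),
        parental_visits=(), attendance=0.70, n_attendance_profiles=8,
        n_pcs=5)
    return replace(base, **overrides)


@dataclass
class SyntheticCohort:
    """Generated records plus the ground truth that produced them."""

    growth: pd.DataFrame
    individuals: pd.DataFrame
    panel: DosagePanel
    score: pd.Series
    true_childhood_coefs: pd.DataFrame
    true_infancy_coefs: pd.DataFrame | None
    params: SimulationParams
    seed: int


def simulate_genotypes(n: int, eafs=None, seed: int = 0, snp_ids=None,
                       jitter: float = 0.0,
                       metadata: pd.DataFrame | None = None) -> DosagePanel:
    """Independent binomial(2, EAF) dosages per SNP.

    ``jitter > 0`` adds truncated Gaussian noise to mimic the
    non-integrality of imputed dosages (kept inside [0, 2]).
    """
    metadata = metadata if metadata is not None else load_snp_metadata()
    if eafs is None:
        eafs = metadata["eaf_alspac"].to_numpy(dtype=float)
        snp_ids = list(metadata.index)
    eafs = np.asarray(eafs, dtype=float)
    if snp_ids is None:
        snp_ids = [f"snp{j}" for j in range(len(eafs))]
    rng = np.random.default_rng(seed)
    dosages = rng.binomial(2, eafs[None, :], size=(n, len(eafs))).astype(float)
    if jitter > 0:
        dosages = np.clip(dosages + rng.normal(0, jitter, dosages.shape),
                          0.0, 2.0)
    ids = [f"ind{i:05d}" for i in range(n)]
    return DosagePanel(ids, list(snp_ids), dosages, metadata=metadata)


def _attendance_profiles(rng, n_visits, attendance, n_profiles, min_size):
    profiles = []
    for _ in range(n_profiles):
        size = max(min_size, rng.binomial(n_visits, attendance))
        idx = np.sort(rng.choice(n_visits, size=min(size, n_visits),
                                 replace=False))
        profiles.append(idx)
    return profiles


def _car_chol(ages, rho):
    R = rho ** np.abs(ages[:, None] - ages[None, :])
    return np.linalg.cholesky(R)


def simulate_cohort(params: SimulationParams, seed: int = 0,
                    panel: DosagePanel | None = None) -> SyntheticCohort:
    """Generate one cohort; identical (params, seed) give byte-identical
    output tables.  A pre-drawn dosage ``panel`` may be supplied (its
    individual count must match ``params.n``); otherwise genotypes are
    drawn from the preset's allele frequencies."""
    rng = np.random.default_rng(seed)
    n = params.n
    meta = load_snp_metadata()
    eafs = meta[params.eaf_column].to_numpy(dtype=float)

    if panel is None:
        ids = [f"{params.cohort_id}_{i:05d}" for i in range(n)]
        panel = DosagePanel(ids, list(meta.index),
                            _draw_dosages(rng, n, eafs, params.dosage_jitter),
                            metadata=meta)
    else:
        if panel.n_individuals != n:
            raise ValueError("panel size does not match params.n")
        ids = [str(i) for i in panel.individual_ids]
    score = pd.Series(panel.dosages.sum(axis=1),
                      index=pd.Index(ids, name="individual_id"),
                      name="allelic_score")
    score_c = score.to_numpy() - 2.0 * eafs.sum()

    sex = np.where(rng.random(n) < params.sex_ratio_male, "male", "female")

    basis = bmi_height_basis()
    mu = np.asarray(childhood_mean_coefficients())
    g_coef = calibrate_genetic_profile(params.g15, params.ar_shift_per_allele,
                                       re_sd=tuple(params.re_sd))
    re_sd = np.asarray(params.re_sd)
    b = rng.normal(0.0, 1.0, (n, len(re_sd))) * re_sd[None, :]
    child_coefs = np.tile(mu, (n, 1)) + score_c[:, None] * g_coef[None, :]
    # random effects sit on columns const, age_c, age_c2, tp2_3
    re_cols = [0, 1, 2, 4]
    for j, col in enumerate(re_cols):
        child_coefs[:, col] += b[:, j]

    hmu = np.asarray(height_mean_coefficients())
    hb = rng.normal(0.0, 1.0, (n, 2)) * np.asarray(params.height_re_sd)[None, :]
    height_coefs = np.tile(hmu, (n, 1))
    # genetic height profile slope*(t-1) = slope*age_c + 7*slope (a = t-8)
    height_coefs[:, 0] += hb[:, 0] + score_c * params.height_g_slope * 7.0
    height_coefs[:, 1] += hb[:, 1] + score_c * params.height_g_slope

    infancy_coefs = None
    if params.infancy_schedule:
        ibasis = infancy_basis()
        imu = np.stack([np.asarray(infancy_mean_coefficients(s)) for s in sex])
        ib = (rng.normal(0.0, 1.0, (n, len(params.infancy_re_sd)))
              * np.asarray(params.infancy_re_sd)[None, :])
        infancy = imu.copy()
        infancy[:, :3] += ib
        infancy[:, 1] += score_c * params.ap_effect_slope
        infancy_coefs = pd.DataFrame(infancy, index=pd.Index(ids, name="individual_id"),
                                     columns=list(ibasis.names))

    # visit attendance
    child_sched = np.asarray(params.childhood_schedule, dtype=float)
    profiles = _attendance_profiles(rng, len(child_sched), params.attendance,
                                    params.n_attendance_profiles, min_size=3)
    assign = rng.integers(0, len(profiles), size=n)
    parental = np.isin(child_sched, np.asarray(params.parental_visits))

    frames = []
    for k, prof in enumerate(profiles):
        members = np.flatnonzero(assign == k)
        if members.size == 0:
            continue
        ages = child_sched[prof]
        ni, m = len(ages), members.size
        D = basis.design(ages)
        mean_bmi = child_coefs[members] @ D.T
        L = _car_chol(ages, params.rho)
        mult = np.where(parental[prof], params.parental_noise_mult, 1.0)
        e_bmi = rng.standard_normal((m, ni)) @ L.T * (params.sigma * mult)
        bmi_vals = mean_bmi + e_bmi
        mean_h = height_coefs[members] @ D.T
        e_h = rng.standard_normal((m, ni)) @ L.T * (params.height_sigma * mult)
        h_vals = mean_h + e_h
        w_vals = bmi_vals * (h_vals / 100.0) ** 2
        src = np.where(parental[prof], "parental_report", "clinic")
        for measure, vals in (("bmi", bmi_vals), ("height", h_vals),
                              ("weight", w_vals)):
            frames.append(pd.DataFrame({
                "individual_id": np.repeat([ids[i] for i in members], ni),
                "sex": np.repeat(sex[members], ni),
                "age": np.tile(ages, m),
                "measure": measure,
                "value": vals.reshape(-1),
                "source": np.tile(src, m),
            }))

    if params.infancy_schedule:
        inf_sched = np.asarray(params.infancy_schedule, dtype=float)
        iprofiles = _attendance_profiles(rng, len(inf_sched),
                                         params.infancy_attendance,
                                         max(4, params.n_attendance_profiles // 2),
                                         min_size=2)
        iassign = rng.integers(0, len(iprofiles), size=n)
        ibasis = infancy_basis()
        icoefs = infancy_coefs.to_numpy()
        for k, prof in enumerate(iprofiles):
            members = np.flatnonzero(iassign == k)
            if members.size == 0:
                continue
            ages = inf_sched[prof]
            ni, m = len(ages), members.size
            D = ibasis.design(ages)
            mean_bmi = icoefs[members] @ D.T
            L = _car_chol(ages, params.rho)
            e = rng.standard_normal((m, ni)) @ L.T * params.infancy_sigma
            vals = mean_bmi + e
            frames.append(pd.DataFrame({
                "individual_id": np.repeat([ids[i] for i in members], ni),
                "sex": np.repeat(sex[members], ni),
                "age": np.tile(ages, m),
                "measure": "bmi",
                "value": vals.reshape(-1),
                "source": "clinic",
            }))

    growth = pd.concat(frames, ignore_index=True)
    growth["cohort_id"] = params.cohort_id
    growth = growth.sort_values(
        ["individual_id", "age", "measure"]).reset_index(drop=True)

    # gross recording errors (unit mix-ups, digit slips): far outside the
    # plausible range so a sex/age-bin 4SD screen can recognise them
    if params.implausible_rate > 0:
        bad = rng.random(len(growth)) < params.implausible_rate
        factors = rng.choice([0.3, 2.6], size=int(bad.sum()))
        growth.loc[bad, "value"] = growth.loc[bad, "value"] * factors
        log.debug("injected %d implausible values", int(bad.sum()))

    # per-individual covariates
    male = (sex == "male").astype(float)
    ga = np.clip(rng.normal(39.5, 1.7, n), 30.0, 44.0)
    bw = (3.41 + 0.11 * male + 0.10 * (ga - 39.5)
          + params.birth_effect * score_c + rng.normal(0, 0.42, n))
    bl = (50.4 + 0.7 * male + 0.55 * (ga - 39.5) + rng.normal(0, 2.2, n))
    individuals = pd.DataFrame({
        "individual_id": ids, "sex": sex,
        "birth_weight": np.round(bw, 3),
        "birth_length": np.round(bl, 1),
        "gestational_age": np.round(ga, 1),
        "cohort_id": params.cohort_id,
    })
    for j in range(params.n_pcs):
        individuals[f"pc{j + 1}"] = rng.normal(0, 1, n)

    return SyntheticCohort(
        growth=growth, individuals=individuals, panel=panel, score=score,
        true_childhood_coefs=pd.DataFrame(
            child_coefs, index=pd.Index(ids, name="individual_id"),
            columns=list(basis.names)),
        true_infancy_coefs=infancy_coefs,
        params=params, seed=seed)


def _draw_dosages(rng, n, eafs, jitter):
    dosages = rng.binomial(2, eafs[None, :], size=(n, len(eafs))).astype(float)
    if jitter > 0:
        dosages = np.clip(dosages + rng.normal(0, jitter, dosages.shape),
                          0.0, 2.0)
    return dosages


def simulate_trajectories(panel: DosagePanel, params: SimulationParams,
                          seed: int = 0) -> SyntheticCohort:
    """Generate growth records for an existing dosage panel."""
    return simulate_cohort(params, seed=seed, panel=panel)


def simulate_two_cohorts(seed: int = 0, n_dense: int = 2000,
                         n_sparse: int = 600):
    """The default two-cohort study: dense and sparse presets with
    independent sub-seeds derived from ``seed``."""
    ss = np.random.SeedSequence(seed).spawn(2)
    dense = simulate_cohort(alspac_like(n=n_dense),
                            seed=int(ss[0].generate_state(1)[0] % (2**31)))
    sparse = simulate_cohort(raine_like(n=n_sparse),
                             seed=int(ss[1].generate_state(1)[0] % (2**31)))
    return dense, sparse


def ground_truth_milestones(cohort: SyntheticCohort,
                            kind: str = "ar") -> pd.DataFrame:
    """Analytic milestones of the *true* individual curves.

    Uses exactly the same derivative-root algebra as the milestone module,
    so it is the oracle for milestone-recovery tests.
    """
    if kind == "ar":
        coefs, basis, finder = (cohort.true_childhood_coefs,
                                bmi_height_basis(), find_adiposity_rebound)
    elif kind == "ap":
        if cohort.true_infancy_coefs is None:
            raise ValueError("cohort has no infancy ground truth")
        coefs, basis, finder = (cohort.true_infancy_coefs, infancy_basis(),
                                find_adiposity_peak)
    else:
        raise ValueError("kind must be 'ap' or 'ar'")
    rows = []
    for uid, row in zip(coefs.index, coefs.to_numpy()):
        ms = finder(basis.curve(row), individual_id=uid)
        rows.append((uid, ms.kind, ms.age, ms.bmi, ms.valid,
                     ms.reason_invalid))
    return pd.DataFrame(rows, columns=["individual_id", "kind", "age", "bmi",
                                       "valid", "reason_invalid"])
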