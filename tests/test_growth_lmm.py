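"""Mixed-model machinery: likelihood, LRT, curves, per-allele effects."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2, multivariate_normal

from bmigrowth import growth_lmm as gl
from bmigrowth.milestones import find_adiposity_rebound
from bmigrowth.spline_basis import bmi_height_basis

from conftest import make_growth_frame


def _tiny_instance(seed=0, n_ind=4):
    rng = np.random.default_rng(seed)
    ids, ages = [], []
    for i in range(n_ind):
        ni = 3 + (i % 2)
        ids += [f"i{i}"] * ni
        ages += list(np.sort(rng.uniform(1, 16, ni)))
    ids, ages = np.array(ids), np.array(ages)
    n = len(ages)
    X = np.column_stack([np.ones(n), ages, ages**2])
    Z = X[:, :2]
    y = rng.normal(17, 1, n)
    return y, X, Z, ids, ages


def test_marginal_loglik_matches_dense_mvn():
    """Blockwise marginal log-likelihood equals a dense multivariate
    normal evaluation with the block-diagonal covariance (<= 1e-6)."""
    y, X, Z, ids, ages = _tiny_instance()
    beta = np.array([16.0, -0.4, 0.04])
    G = np.array([[1.3, 0.08], [0.08, 0.05]])
    sigma2, rho = 0.3, 0.85
    ll = gl.marginal_loglik(y, X, Z, ids, ages, beta, G, sigma2, rho)
    n = len(y)
    cov = np.zeros((n, n))
    for uid in np.unique(ids):
        m = ids == uid
        ai = ages[m]
        cov[np.ix_(m, m)] = (Z[m] @ G @ Z[m].T
                             + sigma2 * rho**np.abs(ai[:, None] - ai[None, :]))
    dense = multivariate_normal.logpdf(y, mean=X @ beta, cov=cov)
    assert abs(ll - dense) < 1e-6


def _sim_model_data(n=120, seed=3, rho=0.9, genetic=True, sigma=0.5):
    """Data drawn exactly from the fitted model family, one schedule."""
    rng = np.random.default_rng(seed)
    basis = bmi_height_basis()
    ages = np.array([1.2, 2.5, 4.5, 5.9, 7.5, 9.9, 11.8, 14.0, 16.0])
    D = basis.design(ages)
    mu = np.array([17.0, 0.4, 0.03, 0.002, -0.05, 0.01, 0.01])
    re_sd = np.array([1.0, 0.12, 0.02, 0.0005])
    R = rho**np.abs(ages[:, None] - ages[None, :]) if rho > 0 else np.eye(len(ages))
    L = np.linalg.cholesky(R)
    rows = []
    for i in range(n):
        score = rng.binomial(64, 0.45)
        c = mu.copy()
        for sd_, col in zip(re_sd, (0, 1, 2, 4)):
            c[col] += rng.normal(0, sd_)
        yv = D @ c + sigma * (L @ rng.standard_normal(len(ages)))
        for a, v in zip(ages, yv):
            rows.append((f"i{i:03d}", "female", a, "bmi", v, "clinic",
                         float(score)))
    return pd.DataFrame(rows, columns=["individual_id", "sex", "age",
                                       "measure", "value", "source",
                                       "allelic_score"])


@pytest.fixture(scope="module")
def ml_fits():
    """Nested ML fits (with and without genetic terms) on null data."""
    df = _sim_model_data(n=100, seed=8)
    basis = bmi_height_basis()
    full = gl.fit_growth_model(
        df, gl.GrowthModelSpec(basis=basis, genetic="allelic_score"),
        reml=False, n_starts=1)
    reduced = gl.fit_growth_model(
        df, gl.GrowthModelSpec(basis=basis, genetic=None),
        reml=False, n_starts=1)
    return full, reduced


def test_fit_loglik_consistent_with_marginal(ml_fits):
    """The profiled ML objective and the direct marginal likelihood agree
    at the fitted parameters."""
    full, _ = ml_fits
    df = full._data
    X, _, Z, _ = gl.build_design(df, full.spec)
    ll = gl.marginal_loglik(df["value"].to_numpy(), X, Z,
                           df["individual_id"].to_numpy(),
                           df["age"].to_numpy(),
                           full.fe_params.to_numpy(), full.G,
                           full.sigma2, full.rho)
    assert ll == pytest.approx(full.loglik, abs=1e-6)


def test_lrt_identical_models(ml_fits):
    full, _ = ml_fits
    dev, df_, p = gl.lrt_genetic_effect(full, full)
    assert dev == 0.0 and p == 1.0


def test_lrt_chi_square_oracle(ml_fits):
    """Deviance, df and p tie together through the chi-square upper tail;
    the genetic block contributes one parameter per basis column."""
    full, reduced = ml_fits
    dev, df_, p = gl.lrt_genetic_effect(full, reduced)
    assert df_ == 7  # main effect (score x const) + 6 interactions
    assert dev >= 0
    assert p == pytest.approx(float(chi2.sf(dev, df_)), rel=1e-12)
    # frozen oracle for the tail computation itself
    assert float(chi2.sf(15.5, 8)) == pytest.approx(0.05012205, abs=1e-7)


def test_lrt_requires_ml(bmi_fit):
    with pytest.raises(ValueError, match="ML"):
        gl.lrt_genetic_effect(bmi_fit, bmi_fit)


def test_individual_curve_matches_conditional_fit(ml_fits):
    """Evaluating an individual's curve at the observed ages reproduces
    the conditional fitted values to numerical precision."""
    full, _ = ml_fits
    fitted = full.fitted_values(conditional=True)
    df = full._data
    for uid in list(full.blups.index)[:10]:
        curve = gl.individual_curve(full, uid)
        sub = df[df["individual_id"] == uid]
        np.testing.assert_allclose(curve(sub["age"].to_numpy()),
                                   fitted[sub.index].to_numpy(),
                                   rtol=0, atol=1e-8)


def test_zero_blup_curve_is_population_curve(ml_fits):
    full, _ = ml_fits
    uid = full.blups.index[0]
    fake = full.blups.copy()
    fake.loc[uid] = 0.0
    patched = gl.GrowthModelFit(**{**full.__dict__, "blups": fake})
    score = float(full.individual_attrs.loc[uid, "allelic_score"])
    pop = gl.population_curve(full, score=score)
    ind = gl.individual_curve(patched, uid)
    t = np.linspace(1.5, 16.5, 40)
    np.testing.assert_allclose(ind(t), pop(t), atol=1e-10)


def test_effect_at_age_equals_prediction_difference(ml_fits):
    """The per-allele effect at age t equals the difference between
    population curves at score s+1 and s (brute-force oracle)."""
    full, _ = ml_fits
    for age in (2.0, 8.0, 15.0):
        beta, se = gl.effect_at_age(full, age)
        diff = (gl.population_curve(full, score=30.0)(age)
                - gl.population_curve(full, score=29.0)(age))
        assert beta == pytest.approx(float(diff), abs=1e-10)
        assert se > 0


def test_effect_at_age_outside_support_fatal(ml_fits):
    full, _ = ml_fits
    with pytest.raises(ValueError, match="support"):
        gl.effect_at_age(full, 25.0)


def test_independent_residuals_give_small_rho():
    """Data generated with rho = 0 yield a near-zero CAR(1) estimate."""
    df = _sim_model_data(n=500, seed=5, rho=0.0, genetic=False)
    fit = gl.fit_growth_model(
        df, gl.GrowthModelSpec(basis=bmi_height_basis(), genetic=None),
        reml=True, n_starts=1)
    assert fit.converged
    assert fit.rho < 0.1


def test_reml_invariant_to_column_rescaling():
    """Rescaling a fixed-effect column rescales its coefficient and leaves
    the restricted likelihood unchanged."""
    df = _sim_model_data(n=80, seed=9)
    basis = bmi_height_basis()
    spec = gl.GrowthModelSpec(basis=basis, genetic="allelic_score",
                              interaction=False)
    fit1 = gl.fit_growth_model(df, spec, reml=True, n_starts=1)
    df2 = df.copy()
    df2["allelic_score"] = df2["allelic_score"] * 10.0
    fit2 = gl.fit_growth_model(df2, spec, reml=True, n_starts=1)
    assert fit2.loglik == pytest.approx(fit1.loglik, abs=5e-3)
    assert fit2.fe_params["allelic_score"] == pytest.approx(
        fit1.fe_params["allelic_score"] / 10.0, rel=1e-3)


def test_blup_shrinkage_with_fewer_observations():
    """Individuals observed less often have random-effect predictions
    shrunk harder towards zero (|BLUP| increases with n obs)."""
    rng = np.random.default_rng(14)
    basis = bmi_height_basis()
    all_ages = np.array([1.2, 2.5, 4.5, 5.9, 7.5, 9.9, 11.8, 14.0, 16.0])
    mu = np.array([17.0, 0.4, 0.03, 0.002, -0.05, 0.01, 0.01])
    rows = []
    for i in range(300):
        k = rng.choice([3, 9])
        ages = np.sort(rng.choice(all_ages, size=k, replace=False))
        c = mu.copy()
        c[0] += rng.normal(0, 1.2)
        yv = basis.design(ages) @ c + rng.normal(0, 0.4, k)
        for a, v in zip(ages, yv):
            rows.append((f"i{i}", "female", a, "bmi", v))
    df = pd.DataFrame(rows, columns=["individual_id", "sex", "age",
                                     "measure", "value"])
    fit = gl.fit_growth_model(
        df, gl.GrowthModelSpec(basis=basis, genetic=None,
                               random_terms=("const",)),
        reml=True, n_starts=1)
    nobs = df.groupby("individual_id").size()
    mag = fit.blups["const"].abs()
    few = mag[nobs[mag.index] == 3].mean()
    many = mag[nobs[mag.index] == 9].mean()
    assert many > few


def test_nonconverged_fit_refused(ml_fits):
    full, _ = ml_fits
    broken = gl.GrowthModelFit(**{**full.__dict__, "converged": False})
    with pytest.raises(RuntimeError, match="non-converged"):
        gl.effect_at_age(broken, 8.0)


def test_min_individuals_floor():
    df = make_growth_frame(["a"] * 3 + ["b"] * 3, [1.5, 3.0, 5.0] * 2,
                           [17, 16, 15.5, 17.2, 16.1, 15.8])
    with pytest.raises(ValueError, match="individuals"):
        gl.fit_growth_model(df, gl.GrowthModelSpec(basis=bmi_height_basis(),
                                                   genetic=None))


def test_save_load_roundtrip(tmp_path, ml_fits):
    full, _ = ml_fits
    path = tmp_path / "fit.json"
    gl.save_fit(full, path)
    back = gl.load_fit(path, bmi_height_basis())
    assert back.loglik == pytest.approx(full.loglik)
    assert back.rho == pytest.approx(full.rho)
    pd.testing.assert_frame_equal(back.blups, full.blups, check_like=True)
    uid = full.blups.index[3]
    t = np.linspace(1.5, 16.5, 20)
    np.testing.assert_allclose(gl.individual_curve(back, uid)(t),
                               gl.individual_curve(full, uid)(t), atol=1e-9)
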