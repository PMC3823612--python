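"""Semi-parametric linear mixed models for growth trajectories.

The model for individual i observed at ages t_i is

    y_i = X_i beta + Z_i b_i + e_i,
    b_i ~ N(0, G),   e_i ~ N(0, sigma^2 R_i(rho)),
    R_i(rho)[s, t] = rho ** |age_s - age_t|           (continuous AR(1)),

where X_i holds the spline basis columns, time-independent covariates and
(optionally) a genetic term interacted with every basis column, and Z_i is
a subset of the basis columns carrying individual random effects.  The
marginal covariance of y_i is Z_i G Z_i' + sigma^2 R_i(rho).

Estimation maximizes the restricted (REML, default) or full (ML) marginal
likelihood.  Fixed effects and sigma^2 are profiled out, so the optimizer
only searches over the Cholesky factor of G/sigma^2 and a logit-transformed
rho.  Individuals sharing a measurement-age pattern share their marginal
covariance, so the likelihood is accumulated per unique age pattern with
batched triangular solves — the dominant cost is one small Cholesky per
pattern per evaluation.

Design columns are rescaled to unit root-mean-square internally (truncated
cubic terms reach ~3e3 at age 17); all reported quantities are transformed
back to the original column scale.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import solve_triangular
from scipy.special import expit, logit
from scipy.stats import chi2

from .spline_basis import SplineBasis, SplineSpec

__all__ = [
    "GrowthModelSpec",
    "GrowthModelFit",
    "fit_growth_model",
    "lrt_genetic_effect",
    "individual_curve",
    "population_curve",
    "effect_at_age",
    "marginal_loglik",
    "build_design",
]

log = logging.getLogger(__name__)

_BIG = 1e10


@dataclass(frozen=True)
class GrowthModelSpec:
    """What to fit: measure, basis, covariates, genetic term, random part.

    ``genetic`` names a per-record column holding the allelic score or a
    single-SNP dosage; with ``interaction=True`` (default) it is crossed
    with every basis column, the score main effect being the interaction
    with the constant column.  ``random_terms`` must be a subset of the
    basis column names.  ``sex`` restricts the fit to one stratum.
    ``age_range`` bounds the records used (open interval); the childhood
    analyses use (1, 17.5) — infancy measurements belong to the separate
    infancy model — and ``None`` falls back to the basis support.
    ``residual_variance_group`` optionally names a categorical record
    column (e.g. the measurement source) whose levels get separate
    residual standard deviations, estimated as ratios to the first level
    in sorted order; parental-report measurements are noisier than clinic
    ones and ignoring that attenuates the CAR(1) estimate.
    """

    basis: SplineBasis
    measure: str = "bmi"
    covariates: tuple = ()
    genetic: str | None = None
    interaction: bool = True
    random_terms: tuple = ("const", "age_c", "age_c2", "tp2_3")
    sex: str | None = None
    age_range: tuple | None = (1.0, 17.5)
    residual_variance_group: str | None = None

    def genetic_columns(self):
        """Genetic term column names; a tuple means several terms (e.g.
        the score plus a score-by-sex product for interaction tests)."""
        if self.genetic is None:
            return ()
        if isinstance(self.genetic, (tuple, list)):
            return tuple(self.genetic)
        return (self.genetic,)

    def genetic_column_names(self, term=None):
        terms = self.genetic_columns() if term is None else (term,)
        names = []
        for g in terms:
            if self.interaction:
                names.extend(f"{g}:{n}" for n in self.basis.names)
            else:
                names.append(g)
        return names


def build_design(data: pd.DataFrame, spec: GrowthModelSpec):
    """Return (X, x_names, Z, z_names) for the records in ``data``."""
    for term in spec.random_terms:
        if term not in spec.basis.names:
            raise ValueError(f"random term {term!r} is not a basis column")
    ages = data["age"].to_numpy(dtype=float)
    B = spec.basis.design(ages)
    blocks = [B]
    names = list(spec.basis.names)
    for c in spec.covariates:
        blocks.append(data[c].to_numpy(dtype=float)[:, None])
        names.append(c)
    for gcol in spec.genetic_columns():
        g = data[gcol].to_numpy(dtype=float)
        if spec.interaction:
            blocks.append(B * g[:, None])
        else:
            blocks.append(g[:, None])
        names.extend(spec.genetic_column_names(gcol))
    X = np.hstack(blocks)
    z_idx = [spec.basis.names.index(t) for t in spec.random_terms]
    Z = B[:, z_idx]
    return X, names, Z, list(spec.random_terms)


class _Block:
    """All individuals sharing one (age, variance-group) pattern."""

    __slots__ = ("ids", "ages", "absdiff", "Z", "Xs", "ys", "gpat", "ni", "m")

    def __init__(self, ids, ages, Z, Xs, ys, gpat):
        self.ids = ids
        self.ages = ages
        self.absdiff = np.abs(ages[:, None] - ages[None, :])
        self.Z = Z
        self.Xs = Xs          # (m, ni, p)
        self.ys = ys          # (m, ni)
        self.gpat = gpat      # (ni,) variance-group codes
        self.m, self.ni = ys.shape


def _make_blocks(ids, X, Z, y, ages, gcodes):
    """Group records by individual, then individuals by pattern."""
    codes, uniques = pd.factorize(ids)
    order = np.lexsort((ages, codes))
    codes, X, Z, y = codes[order], X[order], Z[order], y[order]
    ages, gcodes = ages[order], gcodes[order]
    boundaries = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate(([0], boundaries))
    stops = np.concatenate((boundaries, [len(codes)]))
    patterns = {}
    for s, e in zip(starts, stops):
        key = np.round(ages[s:e], 6).tobytes() + gcodes[s:e].tobytes()
        patterns.setdefault(key, []).append((s, e))
    blocks = []
    for members in patterns.values():
        s0, e0 = members[0]
        ids_b = [uniques[codes[s]] for s, _ in members]
        Xs = np.stack([X[s:e] for s, e in members])
        ys = np.stack([y[s:e] for s, e in members])
        blocks.append(_Block(ids_b, ages[s0:e0].copy(), Z[s0:e0].copy(),
                             Xs, ys, gcodes[s0:e0].copy()))
    return blocks


def _chol_from_theta(theta, q):
    L = np.zeros((q, q))
    L[np.diag_indices(q)] = np.exp(np.clip(theta[:q], -15.0, 15.0))
    if q > 1:
        L[np.tril_indices(q, -1)] = theta[q:q * (q + 1) // 2]
    return L


def _n_theta(q, n_groups=1):
    return q * (q + 1) // 2 + (n_groups - 1) + 1


def _accumulate(theta, blocks, p, q, n_groups=1):
    """One pass over all blocks: GLS building blocks and log-determinant."""
    L = _chol_from_theta(theta, q)
    Gs = L @ L.T
    nchol = q * (q + 1) // 2
    mults = np.ones(n_groups)
    if n_groups > 1:
        mults[1:] = np.exp(np.clip(theta[nchol:nchol + n_groups - 1],
                                   -10.0, 10.0))
    rho = float(expit(theta[-1]))
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    ytVy = 0.0
    logdet = 0.0
    N = 0
    for blk in blocks:
        R = rho**blk.absdiff if rho > 0 else np.eye(blk.ni)
        if n_groups > 1:
            sd = mults[blk.gpat]
            R = R * np.outer(sd, sd)
        V = blk.Z @ Gs @ blk.Z.T + R
        try:
            C = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return None
        Xflat = blk.Xs.transpose(1, 0, 2).reshape(blk.ni, blk.m * p)
        A = solve_triangular(C, Xflat, lower=True, check_finite=False)
        A2 = A.reshape(blk.ni * blk.m, p)
        b = solve_triangular(C, blk.ys.T, lower=True, check_finite=False)
        b2 = b.reshape(-1)
        XtVX += A2.T @ A2
        XtVy += A2.T @ b2
        ytVy += float(b2 @ b2)
        logdet += 2.0 * blk.m * float(np.log(np.diag(C)).sum())
        N += blk.m * blk.ni
    return XtVX, XtVy, ytVy, logdet, N, Gs, rho, mults


def _neg_profile_ll(theta, blocks, p, q, n_groups, reml):
    acc = _accumulate(theta, blocks, p, q, n_groups)
    if acc is None:
        return _BIG
    XtVX, XtVy, ytVy, logdet, N, _, _, _ = acc
    try:
        Cxx = np.linalg.cholesky(XtVX)
    except np.linalg.LinAlgError:
        return _BIG
    u = solve_triangular(Cxx, XtVy, lower=True, check_finite=False)
    rss = ytVy - float(u @ u)
    if not np.isfinite(rss) or rss <= 0:
        return _BIG
    two_pi = np.log(2.0 * np.pi)
    if reml:
        df = N - p
        s2 = rss / df
        logdet_xx = 2.0 * float(np.log(np.diag(Cxx)).sum())
        val = 0.5 * (df * two_pi + df * np.log(s2) + logdet + logdet_xx + df)
    else:
        s2 = rss / N
        val = 0.5 * (N * two_pi + N * np.log(s2) + logdet + N)
    return val if np.isfinite(val) else _BIG


@dataclass
class GrowthModelFit:
    """A converged (or flagged) mixed-model fit.

    ``G`` is the random-effect covariance on the response scale (it
    already includes sigma^2), ordered like ``random_names``;  ``blups``
    holds the predicted random effects per individual on the same scale.
    """

    spec: GrowthModelSpec
    fe_params: pd.Series
    fe_cov: pd.DataFrame
    G: np.ndarray
    sigma2: float
    rho: float
    loglik: float
    reml: bool
    n_individuals: int
    n_obs: int
    converged: bool
    aic: float
    blups: pd.DataFrame
    random_names: list
    individual_attrs: pd.DataFrame = field(repr=False)
    residual_sd_ratios: dict = field(default_factory=dict)
    theta: np.ndarray = field(repr=False, default=None)
    _data: pd.DataFrame = field(repr=False, default=None)

    @property
    def n_fixed(self) -> int:
        return len(self.fe_params)

    @property
    def n_params(self) -> int:
        q = len(self.random_names)
        ng = max(1, len(self.residual_sd_ratios))
        return self.n_fixed + _n_theta(q, ng) + 1  # + sigma^2

    def marginal_residuals(self) -> pd.Series:
        X, names, _, _ = build_design(self._data, self.spec)
        fitted = X @ self.fe_params.to_numpy()
        return pd.Series(self._data["value"].to_numpy() - fitted,
                         index=self._data.index)

    def fitted_values(self, conditional: bool = True) -> pd.Series:
        X, _, Z, _ = build_design(self._data, self.spec)
        fitted = X @ self.fe_params.to_numpy()
        if conditional:
            b = self.blups.reindex(self._data["individual_id"]).to_numpy()
            fitted = fitted + np.einsum("ij,ij->i", Z, b)
        return pd.Series(fitted, index=self._data.index)


def _prepare_data(records: pd.DataFrame, spec: GrowthModelSpec) -> pd.DataFrame:
    df = records
    if "measure" in df.columns:
        df = df[df["measure"] == spec.measure]
    if spec.sex is not None:
        df = df[df["sex"] == spec.sex]
    lo, hi = spec.age_range if spec.age_range is not None else spec.basis.support
    blo, bhi = spec.basis.support
    lo, hi = max(lo, blo), min(hi, bhi)
    df = df[(df["age"] >= lo) & (df["age"] < hi)]
    df = df.dropna(subset=["value", "age"])
    needed = [c for c in spec.covariates if c in df.columns]
    if needed:
        df = df.dropna(subset=needed)
    if spec.genetic is not None:
        df = df.dropna(subset=list(spec.genetic_columns()))
    # model requires repeated measures
    counts = df.groupby("individual_id")["value"].size()
    keep = counts[counts >= 2].index
    return df[df["individual_id"].isin(keep)].copy()


def fit_growth_model(records: pd.DataFrame, spec: GrowthModelSpec, *,
                     reml: bool = True, n_starts: int = 3, seed: int = 0,
                     min_individuals: int = 30, maxiter: int = 400,
                     theta_start=None) -> GrowthModelFit:
    """Fit the growth LMM by maximizing the (restricted) marginal likelihood.

    ``records`` is a long-format table with columns ``individual_id``,
    ``sex``, ``age``, ``measure``, ``value`` plus any covariate / genetic
    columns named by ``spec`` (time-independent, repeated per record).
    Individuals with fewer than two usable observations are dropped;
    fewer than ``min_individuals`` remaining is an error.  Multiple
    optimizer starts (default 3) guard against local optima;
    ``theta_start`` warm-starts the variance-parameter search, e.g. from
    a nested fit on the same records.
    """
    df = _prepare_data(records, spec)
    n_ind = df["individual_id"].nunique()
    if n_ind < min_individuals:
        raise ValueError(
            f"only {n_ind} individuals with >=2 usable observations "
            f"(floor {min_individuals})")
    X, x_names, Z, z_names = build_design(df, spec)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "fixed-effect design is rank deficient; the data need at least "
            "as many distinct measurement ages as basis columns "
            f"({len(spec.basis.names)})")
    y = df["value"].to_numpy(dtype=float)
    ages = df["age"].to_numpy(dtype=float)
    ids = df["individual_id"].to_numpy()

    group_levels = []
    gcodes = np.zeros(len(df), dtype=np.int64)
    if spec.residual_variance_group is not None:
        col = df[spec.residual_variance_group].astype(str)
        group_levels = sorted(col.unique())
        gcodes = col.map({g: i for i, g in enumerate(group_levels)}).to_numpy()
    n_groups = max(1, len(group_levels))

    # column scaling for numerical conditioning
    sx = np.sqrt(np.mean(X * X, axis=0))
    sx[sx <= 0] = 1.0
    sz = np.sqrt(np.mean(Z * Z, axis=0))
    sz[sz <= 0] = 1.0
    blocks = _make_blocks(ids, X / sx, Z / sz, y, ages, gcodes)
    p, q = X.shape[1], Z.shape[1]
    log.debug("fit: %d individuals, %d obs, %d patterns, p=%d q=%d groups=%d",
              n_ind, len(y), len(blocks), p, q, n_groups)

    theta0 = np.zeros(_n_theta(q, n_groups))
    theta0[:q] = np.log(0.7)      # scaled columns -> modest variance ratios
    theta0[-1] = logit(0.5)
    if theta_start is not None:
        theta_start = np.asarray(theta_start, dtype=float)
        if theta_start.shape == theta0.shape:
            theta0 = theta_start
        else:
            log.warning("theta_start has wrong length; ignored")
    rng = np.random.default_rng(seed)

    def _optimize_from(start):
        """L-BFGS-B with restarts: a line search can abort on the
        finite-difference noise floor of a flat variance ridge, in which
        case a fresh Hessian estimate with a larger step usually
        finishes; convergence is certified when a restart no longer
        improves the objective materially."""
        x, fprev, ok = start, None, False
        res = None
        for round_ in range(4):
            res = optimize.minimize(
                _neg_profile_ll, x, args=(blocks, p, q, n_groups, reml),
                method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": 1e-9, "gtol": 1e-7,
                         "eps": 1e-5 if round_ % 2 == 0 else 1e-4})
            x = res.x
            if fprev is not None and fprev - res.fun < 1e-3:
                ok = True
                break
            fprev = res.fun
        return res, ok

    best, best_ok = None, False
    for s in range(max(1, n_starts)):
        start = theta0 if s == 0 else theta0 + rng.normal(0, 0.5, theta0.shape)
        res, ok = _optimize_from(start)
        if res is not None and np.isfinite(res.fun) and (
                best is None or res.fun < best.fun):
            best, best_ok = res, ok
    if best is None:
        raise RuntimeError("optimizer failed from every start")
    converged = bool(best_ok and best.fun < _BIG / 2)

    acc = _accumulate(best.x, blocks, p, q, n_groups)
    XtVX, XtVy, ytVy, logdet, N, Gs, rho, mults = acc
    Cxx = np.linalg.cholesky(XtVX)
    u = solve_triangular(Cxx, XtVy, lower=True, check_finite=False)
    beta_s = solve_triangular(Cxx.T, u, lower=False, check_finite=False)
    rss = ytVy - float(u @ u)
    dof = N - p if reml else N
    s2 = rss / dof
    inv_xx = np.linalg.inv(XtVX)

    # back to original column scale
    beta = beta_s / sx
    fe_cov = s2 * inv_xx / np.outer(sx, sx)
    G = s2 * (Gs / np.outer(sz, sz))

    # BLUPs: b_i = G* Z_i' V_i^{-1} r_i  (sigma^2 cancels)
    blup_rows, blup_ids = [], []
    for blk in blocks:
        R = rho**blk.absdiff
        if n_groups > 1:
            sd = mults[blk.gpat]
            R = R * np.outer(sd, sd)
        V = blk.Z @ Gs @ blk.Z.T + R
        C = np.linalg.cholesky(V)
        resid = blk.ys - blk.Xs @ beta_s            # (m, ni)
        t1 = solve_triangular(C, resid.T, lower=True, check_finite=False)
        t2 = solve_triangular(C.T, t1, lower=False, check_finite=False)
        b = (Gs @ (blk.Z.T @ t2)).T                 # (m, q), scaled space
        blup_rows.append(b / sz)
        blup_ids.extend(blk.ids)
    blups = pd.DataFrame(np.vstack(blup_rows), index=pd.Index(blup_ids, name="individual_id"),
                         columns=z_names).sort_index()

    loglik = -float(best.fun)
    aic = -2.0 * loglik + 2.0 * (p + _n_theta(q, n_groups) + 1)

    attr_cols = [*spec.covariates, *spec.genetic_columns()]
    attrs = (df.groupby("individual_id")[attr_cols].first()
             if attr_cols else
             pd.DataFrame(index=pd.Index(sorted(df["individual_id"].unique()),
                                         name="individual_id")))

    fit = GrowthModelFit(
        spec=spec,
        fe_params=pd.Series(beta, index=x_names),
        fe_cov=pd.DataFrame(fe_cov, index=x_names, columns=x_names),
        G=G, sigma2=float(s2), rho=float(rho),
        loglik=loglik, reml=reml,
        n_individuals=n_ind, n_obs=int(N),
        converged=converged, aic=float(aic),
        blups=blups, random_names=z_names,
        individual_attrs=attrs,
        residual_sd_ratios=dict(zip(group_levels, mults.tolist())),
        theta=np.array(best.x), _data=df,
    )
    if not converged:
        log.warning("growth model did not converge (status: %s)", best.message)
    return fit


def _require_converged(fit: GrowthModelFit):
    if not fit.converged:
        raise RuntimeError("refusing to use a non-converged fit")


def marginal_loglik(y, X, Z, individual_ids, ages, beta, G, sigma2, rho) -> float:
    """Marginal Gaussian log-likelihood at given parameter values.

    Straight per-individual evaluation of the multivariate normal density
    with covariance ``Z_i G Z_i' + sigma2 * rho**|age_s - age_t|``; used
    both as a public utility and as the reference the fitter's profiled
    objective is checked against.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    Z = np.asarray(Z, float)
    ages = np.asarray(ages, float)
    beta = np.asarray(beta, float)
    ids = np.asarray(individual_ids)
    r = y - X @ beta
    total = 0.0
    for uid in pd.unique(ids):
        m = ids == uid
        Zi, ri, ai = Z[m], r[m], ages[m]
        ni = len(ri)
        R = rho ** np.abs(ai[:, None] - ai[None, :])
        V = Zi @ G @ Zi.T + sigma2 * R
        C = np.linalg.cholesky(V)
        w = solve_triangular(C, ri, lower=True)
        total += -0.5 * (ni * np.log(2 * np.pi)
                         + 2.0 * np.log(np.diag(C)).sum() + float(w @ w))
    return float(total)


def lrt_genetic_effect(fit_full: GrowthModelFit, fit_reduced: GrowthModelFit):
    """Likelihood-ratio test of the genetic fixed effects.

    Both fits must be ML (REML log-likelihoods of models with different
    fixed effects are not comparable), nested, and on the same records.
    Returns ``(deviance, df, p)`` with p from the chi-square upper tail.
    """
    if fit_full.reml or fit_reduced.reml:
        raise ValueError("LRT requires ML fits (reml=False)")
    full_names = set(fit_full.fe_params.index)
    red_names = set(fit_reduced.fe_params.index)
    if not red_names < full_names and red_names != full_names:
        raise ValueError("models are not nested")
    if fit_full.n_obs != fit_reduced.n_obs:
        raise ValueError("fits use different records")
    deviance = 2.0 * (fit_full.loglik - fit_reduced.loglik)
    deviance = max(deviance, 0.0)
    df = fit_full.n_fixed - fit_reduced.n_fixed
    if df == 0:
        return deviance, 0, 1.0
    return deviance, df, float(chi2.sf(deviance, df))


def _basis_coef_for(fit: GrowthModelFit, covariate_values=None, score=0.0,
                    blup=None) -> np.ndarray:
    spec = fit.spec
    coef = fit.fe_params[list(spec.basis.names)].to_numpy().copy()
    gterms = spec.genetic_columns()
    if gterms:
        values = (score if isinstance(score, dict)
                  else {gterms[0]: score})
        for g in gterms:
            val = float(values.get(g, 0.0))
            if spec.interaction:
                coef += val * fit.fe_params[
                    spec.genetic_column_names(g)].to_numpy()
            else:
                coef[0] += val * float(fit.fe_params[g])
    if covariate_values:
        for c in spec.covariates:
            coef[0] += float(covariate_values.get(c, 0.0)) * float(fit.fe_params[c])
    if blup is not None:
        for name, b in zip(fit.random_names, blup):
            coef[spec.basis.names.index(name)] += float(b)
    return coef


def population_curve(fit: GrowthModelFit, covariate_values=None, score=0.0):
    """Population-average curve (PPoly) at given covariates and score."""
    coef = _basis_coef_for(fit, covariate_values, score)
    return fit.spec.basis.curve(coef)


def individual_curve(fit: GrowthModelFit, individual_id):
    """Individual curve: fixed effects at the individual's covariates and
    genetic value plus that individual's predicted random effects."""
    if individual_id not in fit.blups.index:
        raise KeyError(f"unknown individual {individual_id!r}")
    attrs = fit.individual_attrs.loc[individual_id] if len(fit.individual_attrs.columns) else {}
    scores = {g: float(attrs[g]) for g in fit.spec.genetic_columns()}
    covs = {c: float(attrs[c]) for c in fit.spec.covariates}
    blup = fit.blups.loc[individual_id].to_numpy()
    coef = _basis_coef_for(fit, covs, scores, blup)
    return fit.spec.basis.curve(coef)


def effect_at_age(fit: GrowthModelFit, age: float, term=None):
    """Per-allele (per-score-unit) effect on the response at ``age``.

    The effect is the linear combination of the genetic main and
    interaction coefficients with the basis evaluated at ``age``; the
    standard error follows by the delta method from the fixed-effect
    covariance.  ``term`` selects one genetic column when the model has
    several (default: the first).  Returns ``(beta, se)``.
    """
    _require_converged(fit)
    gterms = fit.spec.genetic_columns()
    if not gterms:
        raise ValueError("fit has no genetic term")
    term = term or gterms[0]
    lo, hi = fit.spec.basis.support
    if not (lo < age < hi):
        raise ValueError(f"age {age} outside basis support ({lo}, {hi})")
    gnames = fit.spec.genetic_column_names(term)
    if not fit.spec.interaction:
        beta = float(fit.fe_params[term])
        se = float(np.sqrt(fit.fe_cov.loc[term, term]))
        return beta, se
    c = fit.spec.basis.design([age])[0]
    gb = fit.fe_params[gnames].to_numpy()
    gcov = fit.fe_cov.loc[gnames, gnames].to_numpy()
    return float(c @ gb), float(np.sqrt(c @ gcov @ c))


# ---------------------------------------------------------------------------
# plain-text (JSON) fit serialization for the CLI pipeline


def save_fit(fit: GrowthModelFit, path):
    payload = {
        "measure": fit.spec.measure,
        "basis_names": list(fit.spec.basis.names),
        "covariates": list(fit.spec.covariates),
        "genetic": fit.spec.genetic,
        "interaction": fit.spec.interaction,
        "sex": fit.spec.sex,
        "random_names": list(fit.random_names),
        "fe_params": fit.fe_params.to_dict(),
        "fe_cov": fit.fe_cov.to_numpy().tolist(),
        "G": fit.G.tolist(),
        "sigma2": fit.sigma2,
        "rho": fit.rho,
        "loglik": fit.loglik,
        "reml": fit.reml,
        "n_individuals": fit.n_individuals,
        "n_obs": fit.n_obs,
        "converged": fit.converged,
        "aic": fit.aic,
        "blups": {str(k): v for k, v in
                  zip(fit.blups.index, fit.blups.to_numpy().tolist())},
        "individual_attrs": {str(k): v for k, v in
                             zip(fit.individual_attrs.index,
                                 fit.individual_attrs.to_numpy().tolist())},
        "attr_columns": list(fit.individual_attrs.columns),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_fit(path, basis: SplineBasis) -> GrowthModelFit:
    with open(path) as fh:
        d = json.load(fh)
    spec = GrowthModelSpec(
        basis=basis, measure=d["measure"],
        covariates=tuple(d["covariates"]), genetic=d["genetic"],
        interaction=d["interaction"], random_terms=tuple(d["random_names"]),
        sex=d["sex"])
    names = list(d["fe_params"].keys())
    blups = pd.DataFrame.from_dict(d["blups"], orient="index",
                                   columns=d["random_names"])
    blups.index.name = "individual_id"
    attrs = pd.DataFrame.from_dict(d["individual_attrs"], orient="index",
                                   columns=d["attr_columns"])
    attrs.index.name = "individual_id"
    return GrowthModelFit(
        spec=spec,
        fe_params=pd.Series(d["fe_params"]),
        fe_cov=pd.DataFrame(np.array(d["fe_cov"]), index=names, columns=names),
        G=np.array(d["G"]), sigma2=d["sigma2"], rho=d["rho"],
        loglik=d["loglik"], reml=d["reml"],
        n_individuals=d["n_individuals"], n_obs=d["n_obs"],
        converged=d["converged"], aic=d["aic"],
        blups=blups, random_names=list(d["random_names"]),
        individual_attrs=attrs, _data=None,
    )
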