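"""Cross-sectional regressions and variance-explained curves.

Ordinary least squares links the allelic score to birth measures
(adjusting for gestational age), to the derived milestones (age/BMI at
adiposity peak and rebound), and links milestones to final BMI at 15-17
years.  The time-resolved variance explained by the score comes from the
residual sums of squares of two nested longitudinal fits: per age bin b,

    R^2(b) = 1 - sum_b r_full^2 / sum_b r_reduced^2,

using marginal (fixed-effects-only) residuals — the score is a fixed
effect, so its contribution lives in the marginal mean.  Negative
estimates (Monte-Carlo noise) are floored at zero and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .growth_lmm import GrowthModelFit

__all__ = [
    "AssocResult",
    "linear_assoc",
    "milestone_adjusted_assoc",
    "final_bmi",
    "final_bmi_assoc",
    "variance_explained_curve",
    "results_to_frame",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssocResult:
    """One covariate-adjusted OLS association."""

    outcome: str
    exposure: str
    beta: float
    se: float
    p: float
    n: int
    covariates: tuple = ()
    sex: str | None = None
    cohort: str | None = None

    @property
    def term(self) -> str:
        return f"{self.outcome}~{self.exposure}"

    def ci(self, level: float = 0.95):
        from scipy.stats import norm
        z = norm.ppf(0.5 + level / 2)
        return self.beta - z * self.se, self.beta + z * self.se


def results_to_frame(results) -> pd.DataFrame:
    rows = [{"term": r.term, "beta": r.beta, "se": r.se, "p": r.p, "n": r.n,
             "cohort": r.cohort, "sex": r.sex,
             "covariates": ";".join(r.covariates)} for r in results]
    return pd.DataFrame(rows)


def linear_assoc(df: pd.DataFrame, outcome: str, exposure: str,
                 covariates=(), sex: str | None = None,
                 cohort: str | None = None) -> AssocResult:
    """OLS of ``outcome`` on ``exposure`` adjusting for ``covariates``.

    Complete cases only; a rank-deficient design raises with the column
    list rather than returning unstable estimates.
    """
    covariates = tuple(covariates)
    cols = [outcome, exposure, *covariates]
    sub = df.dropna(subset=cols)
    if len(sub) < len(covariates) + 3:
        raise ValueError(
            f"only {len(sub)} complete cases for {cols} (need >= "
            f"{len(covariates) + 3})")
    X = sm.add_constant(sub[[exposure, *covariates]].astype(float))
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError(f"rank-deficient design: columns {list(X.columns)}")
    res = sm.OLS(sub[outcome].astype(float), X).fit()
    return AssocResult(outcome=outcome, exposure=exposure,
                       beta=float(res.params[exposure]),
                       se=float(res.bse[exposure]),
                       p=float(res.pvalues[exposure]),
                       n=int(res.nobs), covariates=covariates,
                       sex=sex, cohort=cohort)


def milestone_adjusted_assoc(df: pd.DataFrame, outcome: str, exposure: str,
                             partner: str, covariates=(),
                             **kw) -> AssocResult:
    """Score-milestone association further adjusted for the partner
    milestone quantity (age adjusted for BMI at the milestone, or vice
    versa)."""
    return linear_assoc(df, outcome, exposure,
                        covariates=(*covariates, partner), **kw)


def final_bmi(growth: pd.DataFrame, window=(15.0, 17.5)) -> pd.Series:
    """Last observed BMI per individual with age in ``window``.

    Individuals without a measurement in the window are absent from the
    result (and logged)."""
    lo, hi = window
    m = ((growth["measure"] == "bmi") & (growth["age"] >= lo)
         & (growth["age"] <= hi) & growth["value"].notna())
    sub = growth[m].sort_values("age")
    out = sub.groupby("individual_id")["value"].last()
    n_total = growth["individual_id"].nunique()
    if len(out) < n_total:
        log.info("final BMI available for %d of %d individuals",
                 len(out), n_total)
    out.name = "final_bmi"
    return out


def final_bmi_assoc(milestone_values: pd.Series, final: pd.Series,
                    covariates: pd.DataFrame | None = None, **kw):
    """Regress final BMI (15-17 y) on a milestone quantity.

    Returns ``(AssocResult, r_squared)`` where R^2 is the OLS coefficient
    of determination."""
    df = pd.DataFrame({"milestone": milestone_values, "final_bmi": final})
    covs = ()
    if covariates is not None:
        df = df.join(covariates)
        covs = tuple(covariates.columns)
    res = linear_assoc(df, "final_bmi", "milestone", covariates=covs, **kw)
    sub = df.dropna(subset=["milestone", "final_bmi", *covs])
    X = sm.add_constant(sub[["milestone", *covs]].astype(float))
    r2 = float(sm.OLS(sub["final_bmi"].astype(float), X).fit().rsquared)
    return res, r2


def variance_explained_curve(fit_full: GrowthModelFit,
                             fit_reduced: GrowthModelFit,
                             bin_centers=tuple(range(1, 17)),
                             half_width: float = 0.5) -> pd.DataFrame:
    """Per-age-bin R^2 of the genetic terms from two nested fits.

    Both fits must be on identical records; bins default to 1-year bins
    centred on integer ages 1-16.  Empty bins yield missing points.
    """
    if fit_full.n_obs != fit_reduced.n_obs:
        raise ValueError("fits are not on identical records")
    r_full = fit_full.marginal_residuals().to_numpy()
    r_red = fit_reduced.marginal_residuals().to_numpy()
    ages = fit_full._data["age"].to_numpy()
    rows = []
    for c in bin_centers:
        m = (ages >= c - half_width) & (ages < c + half_width)
        if not m.any():
            rows.append((float(c), np.nan, 0))
            continue
        ss_full = float((r_full[m] ** 2).sum())
        ss_red = float((r_red[m] ** 2).sum())
        r2 = 1.0 - ss_full / ss_red if ss_red > 0 else np.nan
        if np.isfinite(r2) and r2 < 0:
            log.debug("R^2 floored at 0 in bin %s (was %.2e)", c, r2)
            r2 = 0.0
        rows.append((float(c), r2, int(m.sum())))
    return pd.DataFrame(rows, columns=["age", "r2", "n"])
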