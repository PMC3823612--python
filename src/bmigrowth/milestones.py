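"""Adiposity peak and rebound from fitted individual BMI curves.

Both milestones are stationary points of an individual's piecewise-cubic
BMI curve (fixed plus predicted random effects): the adiposity peak (AP)
is the curve maximum sought between birth and 2.5 years on the infancy
model, the adiposity rebound (AR) the minimum between 2 and 8 years on the
childhood model.  Because the curves are piecewise cubic, their first
derivative is piecewise quadratic and all stationary points are available
in closed form per segment; no grid search is involved.

A milestone is valid only if a stationary point of the right curvature
lies strictly inside the window: roots at the window boundary indicate a
trend clipped by the window and are flagged, not reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PPoly

from . import qc
from .growth_lmm import GrowthModelFit, GrowthModelSpec, fit_growth_model, individual_curve
from .spline_basis import infancy_basis

__all__ = [
    "Milestone",
    "find_adiposity_peak",
    "find_adiposity_rebound",
    "milestone_table",
    "fit_infancy_model",
    "AP_WINDOW",
    "AR_WINDOW",
]

AP_WINDOW = (0.0, 2.5)
AR_WINDOW = (2.0, 8.0)
_EDGE_TOL = 1e-6


@dataclass(frozen=True)
class Milestone:
    """One derived milestone for one individual.

    ``reason_invalid`` is one of ``no_stationary_point`` (the derivative
    has no root in the window), ``wrong_curvature`` (roots exist but none
    has the required second-derivative sign) or ``boundary`` (all roots sit
    on the window edge).
    """

    individual_id: object
    kind: str                      # "adiposity_peak" | "adiposity_rebound"
    age: float | None
    bmi: float | None
    valid: bool
    reason_invalid: str | None = None


def _find_extremum(curve: PPoly, window, minimum: bool, kind: str,
                   individual_id=None) -> Milestone:
    lo, hi = window
    lo = max(lo, float(curve.x[0]))
    hi = min(hi, float(curve.x[-1]))
    d1 = curve.derivative()
    d2 = d1.derivative()
    roots = d1.roots(extrapolate=False)
    roots = np.unique(np.round(roots[np.isfinite(roots)], 9))
    in_window = roots[(roots >= lo - _EDGE_TOL) & (roots <= hi + _EDGE_TOL)]
    if in_window.size == 0:
        return Milestone(individual_id, kind, None, None, False,
                         "no_stationary_point")
    interior = in_window[(in_window > lo + _EDGE_TOL) & (in_window < hi - _EDGE_TOL)]
    if interior.size == 0:
        return Milestone(individual_id, kind, None, None, False, "boundary")
    curv = d2(interior)
    good = interior[curv > 0] if minimum else interior[curv < 0]
    if good.size == 0:
        return Milestone(individual_id, kind, None, None, False,
                         "wrong_curvature")
    vals = curve(good)
    # extreme BMI wins; ties go to the earliest age
    key = np.lexsort((good, vals if minimum else -vals))
    best = key[0]
    return Milestone(individual_id, kind, float(good[best]), float(vals[best]),
                     True, None)


def find_adiposity_rebound(curve: PPoly, window=AR_WINDOW,
                           individual_id=None) -> Milestone:
    """Minimum of the BMI curve strictly inside ``window`` (default 2-8 y)."""
    return _find_extremum(curve, window, minimum=True,
                          kind="adiposity_rebound", individual_id=individual_id)


def find_adiposity_peak(curve: PPoly, window=AP_WINDOW,
                        individual_id=None) -> Milestone:
    """Maximum of the BMI curve strictly inside ``window`` (default 0-2.5 y)."""
    return _find_extremum(curve, window, minimum=False,
                          kind="adiposity_peak", individual_id=individual_id)


def milestone_table(fit: GrowthModelFit, kind: str, window=None) -> pd.DataFrame:
    """Derive one milestone per individual in ``fit``.

    ``kind`` is ``"ap"`` or ``"ar"``.  Returns a data frame with columns
    individual_id, kind, age, bmi, valid, reason_invalid.
    """
    if kind not in {"ap", "ar"}:
        raise ValueError("kind must be 'ap' or 'ar'")
    finder = find_adiposity_peak if kind == "ap" else find_adiposity_rebound
    window = window or (AP_WINDOW if kind == "ap" else AR_WINDOW)
    rows = []
    for uid in fit.blups.index:
        ms = finder(individual_curve(fit, uid), window=window, individual_id=uid)
        rows.append((ms.individual_id, ms.kind, ms.age, ms.bmi, ms.valid,
                     ms.reason_invalid))
    return pd.DataFrame(rows, columns=["individual_id", "kind", "age", "bmi",
                                       "valid", "reason_invalid"])


def fit_infancy_model(records: pd.DataFrame, spec: GrowthModelSpec | None = None,
                      **fit_kwargs) -> GrowthModelFit:
    """Fit the birth-to-5-years BMI model used for the adiposity peak.

    Only individuals with more than two BMI measures before age 5 are
    included.  The infancy basis is a cubic in age plus one cubic
    truncated term at 1 y, with random effects on the constant, linear and
    quadratic terms — the minimal shape flexibility that can place a peak
    in the first 2.5 years while staying estimable from 3-5 observations.
    """
    eligible = qc.eligible_ids_for_ap(records)
    df = records[records["individual_id"].isin(eligible)]
    df = df[(df["measure"] == "bmi") & (df["age"] >= 0) & (df["age"] < 5.0)]
    if spec is None:
        spec = GrowthModelSpec(
            basis=infancy_basis(), measure="bmi",
            random_terms=("const", "age", "age2"),
            age_range=(0.0, 5.0))
    return fit_growth_model(df, spec, **fit_kwargs)
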