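"""Truncated-power spline bases for childhood growth-curve models.

The childhood BMI and height models use a cubic polynomial in centred age
``a = t - 8`` plus cubic truncated-power terms ``(t - k)+^3`` at knots
2, 8 and 12 years, giving a piecewise cubic curve with continuous first and
second derivatives at every knot.  The weight model shares the knots but is
linear below 2 y, cubic on [2, 8) and [8, 12), and quadratic beyond 12 y;
the drop from cubic to quadratic is enforced by absorbing the ``(t-12)+^3``
column into the two other cubic truncated terms so that the total cubic
coefficient vanishes past the last knot.  A small infancy basis (cubic in
age plus one cubic truncated term at 1 y) supports the birth-to-5-years
model used to locate the adiposity peak.

Every basis can be materialised as a design matrix for regression, or
turned into a :class:`scipy.interpolate.PPoly` piecewise polynomial for a
given coefficient vector, which is what the milestone derivations operate
on (derivative roots are then available analytically per segment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial
from scipy.interpolate import PPoly

__all__ = [
    "truncated_power_term",
    "SplineBasis",
    "SplineSpec",
    "bmi_height_basis",
    "weight_basis",
    "infancy_basis",
]


def truncated_power_term(t, knot: float, power: int):
    """Evaluate the truncated power term ``(t - knot)+^power``.

    Zero at and below the knot, ``(t - knot)**power`` above it.  Using
    integer powers >= 1 guarantees continuity of the first ``power - 1``
    derivatives across the knot.
    """
    if power < 1:
        raise ValueError("truncated power requires power >= 1")
    t = np.asarray(t, dtype=float)
    d = np.clip(t - knot, 0.0, None)
    return d**power


def _shifted_power_coeffs(power: int, shift: float) -> np.ndarray:
    """Ascending coefficients in t of (t - shift)**power."""
    c = np.zeros(power + 1)
    for i in range(power + 1):
        c[i] = math.comb(power, i) * (-shift) ** (power - i)
    return c


@dataclass(frozen=True)
class _Poly:
    """Global polynomial term (t - center)**power."""

    power: int
    center: float = 0.0

    def evaluate(self, t):
        return (np.asarray(t, dtype=float) - self.center) ** self.power

    def coeffs_on(self, lo: float, hi: float) -> np.ndarray:
        return _shifted_power_coeffs(self.power, self.center)


@dataclass(frozen=True)
class _Trunc:
    """Truncated power term (t - knot)+**power."""

    knot: float
    power: int

    def evaluate(self, t):
        return truncated_power_term(t, self.knot, self.power)

    def coeffs_on(self, lo: float, hi: float) -> np.ndarray:
        # segments are aligned to knots, so a segment lies entirely on one side
        if hi <= self.knot + 1e-12:
            return np.zeros(1)
        return _shifted_power_coeffs(self.power, self.knot)


@dataclass(frozen=True)
class _Combo:
    """Fixed linear combination of terms (used for hard constraints)."""

    terms: tuple
    weights: tuple

    def evaluate(self, t):
        out = np.zeros_like(np.asarray(t, dtype=float))
        for w, term in zip(self.weights, self.terms):
            out = out + w * term.evaluate(t)
        return out

    def coeffs_on(self, lo: float, hi: float) -> np.ndarray:
        parts = [w * term.coeffs_on(lo, hi) for w, term in zip(self.weights, self.terms)]
        k = max(len(p) for p in parts)
        out = np.zeros(k)
        for p in parts:
            out[: len(p)] += p
        return out


@dataclass(frozen=True)
class SplineBasis:
    """A fixed set of named basis columns over a support interval."""

    names: tuple
    terms: tuple
    knots: tuple
    support: tuple

    @property
    def n_columns(self) -> int:
        return len(self.terms)

    def design(self, ages) -> np.ndarray:
        """Evaluate all basis columns at ``ages`` (n x k array)."""
        ages = np.asarray(ages, dtype=float)
        return np.column_stack([term.evaluate(ages) for term in self.terms])

    def design_frame(self, ages) -> pd.DataFrame:
        return pd.DataFrame(self.design(ages), columns=list(self.names))

    def breakpoints(self) -> np.ndarray:
        lo, hi = self.support
        inner = [k for k in self.knots if lo < k < hi]
        return np.array([lo, *inner, hi], dtype=float)

    def max_degree(self) -> int:
        deg = 0
        lo, hi = self.support
        for term in self.terms:
            deg = max(deg, len(term.coeffs_on(lo, hi)) - 1)
        return deg

    def curve(self, coef) -> PPoly:
        """Piecewise polynomial for a coefficient vector (one per column).

        Returns a :class:`scipy.interpolate.PPoly` over the basis support
        with breakpoints at the interior knots; derivative roots of the
        returned object are available in closed form per segment.
        """
        coef = np.asarray(coef, dtype=float)
        if coef.shape != (self.n_columns,):
            raise ValueError(
                f"expected {self.n_columns} coefficients, got shape {coef.shape}"
            )
        bp = self.breakpoints()
        kmax = self.max_degree()
        C = np.zeros((kmax + 1, len(bp) - 1))
        for j, (lo, hi) in enumerate(zip(bp[:-1], bp[1:])):
            total = np.zeros(kmax + 1)
            for c, term in zip(coef, self.terms):
                part = c * term.coeffs_on(lo, hi)
                total[: len(part)] += part
            # re-express in the local variable u = t - lo (PPoly convention)
            local = Polynomial(total)(Polynomial([lo, 1.0])).coef
            padded = np.zeros(kmax + 1)
            padded[: len(local)] = local
            C[:, j] = padded[::-1]
        return PPoly(C, bp, extrapolate=False)


def bmi_height_basis(center: float = 8.0, knots=(2.0, 8.0, 12.0),
                     support=(0.5, 18.0)) -> SplineBasis:
    """Basis for the BMI and height models: cubic in centred age plus a
    cubic truncated term at each knot (piecewise cubic, C2-continuous)."""
    knots = tuple(float(k) for k in knots)
    if list(knots) != sorted(set(knots)):
        raise ValueError("knots must be strictly increasing")
    terms = (
        _Poly(0),
        _Poly(1, center),
        _Poly(2, center),
        _Poly(3, center),
        *(_Trunc(k, 3) for k in knots),
    )
    names = (
        "const", "age_c", "age_c2", "age_c3",
        *(f"tp{k:g}_3" for k in knots),
    )
    return SplineBasis(names=names, terms=terms, knots=knots, support=tuple(support))


def weight_basis(center: float = 8.0, knots=(2.0, 8.0, 12.0),
                 support=(0.5, 18.0)) -> SplineBasis:
    """Basis for the weight model: linear below 2 y, cubic on [2, 8) and
    [8, 12), quadratic beyond 12 y.

    The final segment's degree drop is a hard constraint: the coefficient
    of ``(t-12)+^3`` is minus the sum of the other cubic coefficients, so
    the two free cubic columns are ``(t-k)+^3 - (t-12)+^3`` for k in
    {2, 8}.  Linearity below 2 y comes from omitting the global quadratic
    and cubic terms.
    """
    k1, k2, k3 = (float(k) for k in knots)
    terms = (
        _Poly(0),
        _Poly(1, center),
        _Trunc(k1, 2),
        _Combo((_Trunc(k1, 3), _Trunc(k3, 3)), (1.0, -1.0)),
        _Trunc(k2, 2),
        _Combo((_Trunc(k2, 3), _Trunc(k3, 3)), (1.0, -1.0)),
        _Trunc(k3, 2),
    )
    names = (
        "const", "age_c",
        f"tp{k1:g}_2", f"tp{k1:g}_3c",
        f"tp{k2:g}_2", f"tp{k2:g}_3c",
        f"tp{k3:g}_2",
    )
    return SplineBasis(names=names, terms=terms, knots=(k1, k2, k3),
                       support=tuple(support))


def infancy_basis(knot: float = 1.0, support=(0.0, 5.0)) -> SplineBasis:
    """Basis for the birth-to-5-years model used to locate the adiposity
    peak: cubic in age plus one cubic truncated term at 1 y."""
    terms = (
        _Poly(0),
        _Poly(1, 0.0),
        _Poly(2, 0.0),
        _Poly(3, 0.0),
        _Trunc(float(knot), 3),
    )
    names = ("const", "age", "age2", "age3", f"tp{knot:g}_3")
    return SplineBasis(names=names, terms=terms, knots=(float(knot),),
                       support=tuple(support))


_BUILDERS = {
    "bmi_height": bmi_height_basis,
    "weight": weight_basis,
    "infancy": infancy_basis,
}


@dataclass(frozen=True)
class SplineSpec:
    """Serializable description of a basis, used in run configuration.

    ``kind`` selects one of the three model bases; the remaining fields
    override their defaults (knots at {2, 8, 12} years, centring age 8 y
    for the childhood bases).
    """

    kind: str = "bmi_height"
    center: float = 8.0
    knots: tuple = (2.0, 8.0, 12.0)
    support: tuple = (0.5, 18.0)

    def build(self) -> SplineBasis:
        if self.kind == "infancy":
            return infancy_basis(knot=self.knots[0] if self.knots else 1.0,
                                 support=self.support)
        if self.kind not in _BUILDERS:
            raise ValueError(f"unknown basis kind {self.kind!r}")
        return _BUILDERS[self.kind](center=self.center, knots=self.knots,
                                    support=self.support)
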