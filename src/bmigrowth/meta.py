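"""Two-cohort meta-analysis: inverse-variance pooling, Cochran's Q,
Fisher p-value combination, and the Bonferroni policy.

Allelic-score effect sizes from the cohorts are pooled with fixed-effect
inverse-variance weights (w_i = 1/se_i^2); heterogeneity is reported via
Cochran's Q but never switches the pooling to random effects.  Per-SNP
likelihood-ratio p-values are combined without weighting by Fisher's
method (-2 * sum log p against chi-square with 2k df), judged against a
Bonferroni threshold of 0.05 / n_tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2, norm

__all__ = [
    "MetaResult",
    "fixed_effect_meta",
    "cochran_q",
    "fisher_combine",
    "bonferroni_threshold",
    "format_threshold",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetaResult:
    """Pooled fixed-effect estimate with heterogeneity diagnostics."""

    beta: float
    se: float
    p: float
    q: float
    q_df: int
    q_p: float
    method: str
    betas: tuple
    ses: tuple


def _check(betas, ses):
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.shape != ses.shape or betas.ndim != 1:
        raise ValueError("betas and ses must be equal-length vectors")
    if (ses <= 0).any():
        raise ValueError("all standard errors must be positive")
    return betas, ses


def fixed_effect_meta(betas, ses) -> MetaResult:
    """Inverse-variance fixed-effect pooling of per-study estimates.

    A single study passes through with a warning; the pooled p-value is
    two-sided normal.
    """
    betas, ses = _check(betas, ses)
    if len(betas) == 1:
        log.warning("single-study meta-analysis: passing estimate through")
    w = 1.0 / ses**2
    pooled = float((w * betas).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    p = float(2.0 * norm.sf(abs(pooled) / se))
    q, q_df, q_p = cochran_q(betas, ses)
    return MetaResult(beta=pooled, se=se, p=p, q=q, q_df=q_df, q_p=q_p,
                      method="inverse_variance",
                      betas=tuple(betas), ses=tuple(ses))


def cochran_q(betas, ses):
    """Cochran's heterogeneity statistic: Q = sum w_i (b_i - pooled)^2,
    df = k - 1, chi-square upper-tail p (p = 1 for a single study)."""
    betas, ses = _check(betas, ses)
    w = 1.0 / ses**2
    pooled = (w * betas).sum() / w.sum()
    q = float((w * (betas - pooled) ** 2).sum())
    df = len(betas) - 1
    p = float(chi2.sf(q, df)) if df > 0 else 1.0
    return q, df, p


def fisher_combine(pvalues) -> float:
    """Fisher's method: X = -2 sum ln p_i ~ chi-square with 2k df.

    All inputs must lie in (0, 1]; an exact zero is an error (log of
    zero), callers should clip upstream if they can justify it.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("need a non-empty vector of p-values")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    x = -2.0 * np.log(p).sum()
    return float(chi2.sf(x, 2 * len(p)))


def bonferroni_threshold(n_tests: int, fwer: float = 0.05) -> float:
    """Family-wise threshold fwer / n_tests (full precision)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return fwer / n_tests


def format_threshold(threshold: float, sig_figs: int = 2) -> str:
    """Display form at ``sig_figs`` significant figures (0.0015625 ->
    '0.0016')."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    from decimal import Decimal
    d = Decimal(f"{threshold:.{sig_figs}g}")
    return format(d.normalize(), "f")
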