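"""Outlier recoding and analysis-set assembly for anthropometric records.

Implausible BMI, weight and height values are recoded to missing when they
lie more than 4 sample standard deviations from the mean of their sex- and
age-bin-specific cell.  The rule is applied in a single pass with cell
means and SDs computed once on the raw data: a cleaned dataset is never
re-filtered, which keeps the procedure reproducible and order-independent.
Cells with fewer than two records (no SD) and zero-SD cells pass through
unflagged.  Birth measures are covariate-adjusted outcomes elsewhere in
the pipeline and are never 4SD-filtered; the age bins deliberately cover
only the trajectory-modelling range (1, 17.5) years.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AgeBinScheme",
    "default_age_bins",
    "flag_implausible",
    "eligible_for_ap",
    "eligible_ids_for_ap",
]

log = logging.getLogger(__name__)

# half-open strata: 1-1.49, 1.5-2.49, ..., 15.5-16.49, >16.5
DEFAULT_BIN_EDGES = (1.0, 1.5, 2.5, 3.5, 4.5, 5.5, 6.5, 7.5, 8.5, 9.5, 10.5,
                     11.5, 12.5, 13.5, 14.5, 15.5, 16.5, 17.5)


@dataclass(frozen=True)
class AgeBinScheme:
    """Ordered, non-overlapping half-open age intervals [lo, hi)."""

    edges: tuple

    def __post_init__(self):
        e = np.asarray(self.edges, dtype=float)
        if len(e) < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def labels(self):
        return [f"{lo:g}-{hi:g}" for lo, hi in zip(self.edges[:-1], self.edges[1:])]

    def assign(self, ages) -> np.ndarray:
        """Bin index per age; -1 for ages outside the scheme."""
        ages = np.asarray(ages, dtype=float)
        idx = np.searchsorted(np.asarray(self.edges), ages, side="right") - 1
        idx[(ages < self.edges[0]) | (ages >= self.edges[-1])] = -1
        return idx


def default_age_bins() -> AgeBinScheme:
    return AgeBinScheme(DEFAULT_BIN_EDGES)


def flag_implausible(records: pd.DataFrame, scheme: AgeBinScheme | None = None,
                     sd_threshold: float = 4.0):
    """Recode values > ``sd_threshold`` SDs from their cell mean to missing.

    Cells are (sex, measure, age bin); means and sample SDs (ddof=1) come
    from the raw data in one pass.  Returns ``(cleaned, report)`` where
    ``cleaned`` is a copy with flagged values set to NaN and ``report``
    counts flags per cell.  Records outside the bin scheme (infancy and
    birth records) are untouched.
    """
    scheme = scheme or default_age_bins()
    df = records.copy()
    bins = scheme.assign(df["age"].to_numpy())
    inrange = bins >= 0
    flagged = np.zeros(len(df), dtype=bool)
    report_rows = []
    sub = df[inrange]
    labels = scheme.labels()
    for (sex, measure, b), grp in sub.groupby(
            [sub["sex"], sub["measure"], bins[inrange]]):
        vals = grp["value"].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        if ok.sum() < 2:
            log.debug("degenerate QC cell (%s, %s, %s): %d records",
                      sex, measure, labels[b], ok.sum())
            continue
        m = float(np.mean(vals[ok]))
        sd = float(np.std(vals[ok], ddof=1))
        if sd == 0.0:
            continue  # identical values are kept, never mass-flagged
        bad = ok & (np.abs(vals - m) > sd_threshold * sd)
        if bad.any():
            flagged[grp.index[bad]] = True
        report_rows.append((sex, measure, labels[b], int(bad.sum()), int(ok.sum())))
    cleaned = df.copy()
    cleaned.loc[flagged, "value"] = np.nan
    report = pd.DataFrame(report_rows,
                          columns=["sex", "measure", "age_bin", "n_flagged", "n"])
    n_flag = int(flagged.sum())
    if n_flag:
        log.info("QC recoded %d of %d records to missing", n_flag, len(df))
    return cleaned, report


def eligible_for_ap(individual_records: pd.DataFrame,
                    window=(0.0, 5.0)) -> bool:
    """True iff the individual has more than two BMI measures in ``window``.

    The strict inequality matters: exactly two measures is not enough for
    the infancy model's individual curvature.
    """
    lo, hi = window
    df = individual_records
    m = ((df["measure"] == "bmi") & (df["age"] >= lo) & (df["age"] < hi)
         & df["value"].notna())
    return int(m.sum()) > 2


def eligible_ids_for_ap(records: pd.DataFrame, window=(0.0, 5.0)) -> pd.Index:
    """Ids of individuals eligible for adiposity-peak derivation."""
    lo, hi = window
    m = ((records["measure"] == "bmi") & (records["age"] >= lo)
         & (records["age"] < hi) & records["value"].notna())
    counts = records[m].groupby("individual_id")["value"].size()
    return counts[counts > 2].index
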