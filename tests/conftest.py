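"""Shared fixtures: small seeded synthetic cohorts and reusable fits.

Everything is generated programmatically; heavy fits are module/session
scoped so several tests can share one converged model.
"""

import numpy as np
import pandas as pd
import pytest

from bmigrowth import growth_lmm as gl
from bmigrowth import pipeline
from bmigrowth import synthetic_data as sd
from bmigrowth.spline_basis import bmi_height_basis


@pytest.fixture(scope="session")
def small_cohort():
    """Dense-preset cohort, n=250, fixed seed."""
    return sd.simulate_cohort(sd.alspac_like(n=250), seed=20240917)


@pytest.fixture(scope="session")
def analysis_frame(small_cohort):
    df, _ = pipeline.prepare_analysis_frame(
        small_cohort.growth, small_cohort.panel, small_cohort.individuals)
    return df


@pytest.fixture(scope="session")
def bmi_fit(analysis_frame):
    """REML BMI fit with the allelic score on the small cohort."""
    fit = pipeline.fit_trajectory_model(analysis_frame, measure="bmi",
                                        genetic="allelic_score",
                                        n_starts=1, seed=0)
    assert fit.converged
    return fit


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_growth_frame(ids, ages, values, sex="female", measure="bmi",
                      source="clinic"):
    """Small helper to build long-format growth records in tests."""
    n = len(values)
    return pd.DataFrame({
        "individual_id": ids if not np.isscalar(ids) else [ids] * n,
        "sex": [sex] * n,
        "age": ages,
        "measure": [measure] * n,
        "value": values,
        "source": [source] * n,
        "cohort_id": ["test"] * n,
    })
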