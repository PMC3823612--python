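"""Convenience orchestration of the analysis stages.

These helpers chain QC, scoring, model fitting, milestone derivation and
association exactly the way the command-line interface does, so scripted
analyses, the CLI and the test-suite share one code path.  Cohort-specific
conventions live here: a dense-schedule cohort with parental reports gets
the measurement-source indicator as a fixed effect and as a residual-
variance group, a cohort with ancestry PCs gets the first five as
covariates.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import association, milestones, qc
from .genotype_score import DosagePanel, compute_allelic_score
from .growth_lmm import (GrowthModelFit, GrowthModelSpec, fit_growth_model,
                         lrt_genetic_effect)
from .spline_basis import bmi_height_basis, weight_basis

log = logging.getLogger(__name__)

BMI_RANDOM_TERMS = ("const", "age_c", "age_c2", "tp2_3")
WEIGHT_RANDOM_TERMS = ("const", "age_c", "tp2_2")


def prepare_analysis_frame(growth: pd.DataFrame, panel: DosagePanel,
                           individuals: pd.DataFrame | None = None,
                           sd_threshold: float = 4.0):
    """QC the growth records, attach the allelic score and covariates.

    Returns ``(frame, qc_report)``; the frame carries ``allelic_score``,
    a binary ``parental`` indicator and any PC columns found in the
    individual table.
    """
    cleaned, report = qc.flag_implausible(growth, sd_threshold=sd_threshold)
    score = compute_allelic_score(panel)
    df = cleaned.merge(score.rename("allelic_score"),
                       left_on="individual_id", right_index=True, how="left")
    df["parental"] = (df["source"] == "parental_report").astype(float)
    if individuals is not None:
        pcs = [c for c in individuals.columns if c.startswith("pc")]
        if pcs:
            df = df.merge(individuals[["individual_id", *pcs]],
                          on="individual_id", how="left")
    return df, report


def _cohort_covariates(df: pd.DataFrame) -> tuple:
    covs = []
    if df["parental"].nunique() > 1:
        covs.append("parental")
    covs.extend(c for c in df.columns if c.startswith("pc"))
    return tuple(covs)


def model_spec(df: pd.DataFrame, measure: str = "bmi",
               genetic: str | None = "allelic_score",
               sex: str | None = None, interaction: bool = True) -> GrowthModelSpec:
    """The cohort-appropriate model specification for one measure."""
    if measure in {"bmi", "height"}:
        basis, random_terms = bmi_height_basis(), BMI_RANDOM_TERMS
    elif measure == "weight":
        basis, random_terms = weight_basis(), WEIGHT_RANDOM_TERMS
    else:
        raise ValueError(f"unknown measure {measure!r}")
    var_group = "source" if df["parental"].nunique() > 1 else None
    return GrowthModelSpec(
        basis=basis, measure=measure, covariates=_cohort_covariates(df),
        genetic=genetic, interaction=interaction, random_terms=random_terms,
        sex=sex, residual_variance_group=var_group)


def fit_trajectory_model(df: pd.DataFrame, measure: str = "bmi",
                         sex: str | None = None,
                         genetic: str | None = "allelic_score",
                         **fit_kwargs) -> GrowthModelFit:
    spec = model_spec(df, measure=measure, genetic=genetic, sex=sex)
    return fit_growth_model(df, spec, **fit_kwargs)


def genetic_lrt(df: pd.DataFrame, measure: str = "bmi",
                sex: str | None = None, genetic: str = "allelic_score",
                **fit_kwargs):
    """ML fits with and without the genetic terms and their LRT."""
    full = fit_trajectory_model(df, measure=measure, sex=sex,
                                genetic=genetic, reml=False, **fit_kwargs)
    reduced = fit_trajectory_model(df, measure=measure, sex=sex,
                                   genetic=None, reml=False, **fit_kwargs)
    return lrt_genetic_effect(full, reduced), full, reduced


def sex_interaction_lrt(df: pd.DataFrame, measure: str = "bmi",
                        genetic: str = "allelic_score", **fit_kwargs):
    """Pooled-sex LRT for a sex-specific genetic trajectory effect.

    The full model carries the genetic term and its product with a male
    indicator, each interacted with the whole spline; the reduced model
    drops the sex product.  Returns ``(deviance, df, p)`` plus the fits.
    """
    data = df.copy()
    male = (data["sex"] == "male").astype(float)
    data["male"] = male
    data[f"{genetic}_x_male"] = data[genetic] * male
    base = model_spec(data, measure=measure, genetic=genetic)
    spec_red = GrowthModelSpec(**{**base.__dict__,
                                  "covariates": (*base.covariates, "male")})
    spec_full = GrowthModelSpec(**{**spec_red.__dict__,
                                   "genetic": (genetic,
                                               f"{genetic}_x_male")})
    full = fit_growth_model(data, spec_full, reml=False, **fit_kwargs)
    reduced = fit_growth_model(data, spec_red, reml=False, **fit_kwargs)
    return lrt_genetic_effect(full, reduced), full, reduced


def milestone_frame(fit: GrowthModelFit, kind: str,
                    score: pd.Series) -> pd.DataFrame:
    """Valid milestones joined with the allelic score, ready for OLS."""
    tab = milestones.milestone_table(fit, kind)
    tab = tab[tab["valid"]].drop(columns=["valid", "reason_invalid"])
    return tab.merge(score.rename("allelic_score"),
                     left_on="individual_id", right_index=True)


def score_milestone_assocs(ms: pd.DataFrame, sex=None, cohort=None):
    """Score vs age and BMI at a milestone, plus mutually adjusted runs."""
    out = {
        "age": association.linear_assoc(ms, "age", "allelic_score",
                                        sex=sex, cohort=cohort),
        "bmi": association.linear_assoc(ms, "bmi", "allelic_score",
                                        sex=sex, cohort=cohort),
        "age_adj_bmi": association.milestone_adjusted_assoc(
            ms, "age", "allelic_score", "bmi", sex=sex, cohort=cohort),
        "bmi_adj_age": association.milestone_adjusted_assoc(
            ms, "bmi", "allelic_score", "age", sex=sex, cohort=cohort),
    }
    return out
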