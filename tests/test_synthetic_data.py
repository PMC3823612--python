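"""Generator structure, calibration anchors and determinism."""

import numpy as np
import pandas as pd
import pytest

from bmigrowth import milestones as ms
from bmigrowth import synthetic_data as sd
from bmigrowth.genotype_score import load_snp_metadata
from bmigrowth.spline_basis import bmi_height_basis


def test_zero_eaf_gives_zero_dosages():
    panel = sd.simulate_genotypes(50, eafs=np.zeros(32),
                                  snp_ids=list(load_snp_metadata().index),
                                  seed=0)
    assert (panel.dosages == 0).all()


def test_half_eaf_mean_dosage():
    panel = sd.simulate_genotypes(10_000, eafs=np.full(32, 0.5),
                                  snp_ids=list(load_snp_metadata().index),
                                  seed=1)
    se = np.sqrt(0.5 * 0.5 * 2 / 10_000)
    assert abs(panel.dosages[:, 0].mean() - 1.0) < 3 * se


def test_sample_eafs_match_reference_within_3se():
    meta = load_snp_metadata()
    n = 4000
    panel = sd.simulate_genotypes(n, seed=2)
    freqs = panel.dosages.mean(axis=0) / 2.0
    p = meta["eaf_alspac"].to_numpy()
    se = np.sqrt(p * (1 - p) / (2 * n))
    assert (np.abs(freqs - p) < 3.5 * se).mean() > 0.95


def test_noise_free_records_lie_on_true_curves():
    params = sd.alspac_like(
        n=30, re_sd=(0, 0, 0, 0), sigma=0.0, infancy_sigma=0.0,
        infancy_re_sd=(0, 0, 0), height_re_sd=(0, 0), height_sigma=0.0,
        implausible_rate=0.0, g15=0.0, ar_shift_per_allele=0.0,
        height_g_slope=0.0, ap_effect_slope=0.0)
    coh = sd.simulate_cohort(params, seed=3)
    basis = bmi_height_basis()
    mu = np.array(sd.childhood_mean_coefficients())
    bmi = coh.growth[(coh.growth.measure == "bmi") & (coh.growth.age >= 1)]
    np.testing.assert_allclose(
        bmi["value"].to_numpy(),
        basis.curve(mu)(bmi["age"].to_numpy()), atol=1e-9)


def test_residual_lag_correlation_near_rho():
    """Empirical correlation of same-individual residuals ~1 y apart is
    close to the configured CAR(1) rho (moment check at n=2,000)."""
    coh = sd.simulate_cohort(sd.alspac_like(n=2000, implausible_rate=0.0,
                                            parental_noise_mult=1.0),
                             seed=4)
    basis = bmi_height_basis()
    coefs = coh.true_childhood_coefs
    bmi = coh.growth[(coh.growth.measure == "bmi") & (coh.growth.age >= 1)]
    pairs = []
    for uid, grp in bmi.groupby("individual_id"):
        resid = grp["value"].to_numpy() - basis.curve(
            coefs.loc[uid].to_numpy())(grp["age"].to_numpy())
        a = grp["age"].to_numpy()
        for i in range(len(a) - 1):
            if 0.8 <= a[i + 1] - a[i] <= 1.3:
                pairs.append((resid[i], resid[i + 1]))
    pairs = np.asarray(pairs)
    assert len(pairs) > 500
    corr = np.corrcoef(pairs[:, 0], pairs[:, 1])[0, 1]
    assert corr == pytest.approx(0.9, abs=0.05)


def test_ground_truth_milestones_same_algebra():
    coh = sd.simulate_cohort(sd.alspac_like(n=60), seed=5)
    truth = sd.ground_truth_milestones(coh, "ar")
    basis = bmi_height_basis()
    for _, row in truth.head(20).iterrows():
        m = ms.find_adiposity_rebound(basis.curve(
            coh.true_childhood_coefs.loc[row["individual_id"]].to_numpy()))
        assert m.valid == row["valid"]
        if m.valid:
            assert m.age == pytest.approx(row["age"], abs=1e-12)


def test_population_median_rebound_age_near_target():
    """Median individual rebound age stays close to the population-curve
    minimum (a small upward drift is expected: individual minima respond
    to random tilts through the reciprocal of their curvature) and inside
    the published 5.3-6.1 y range."""
    coh = sd.simulate_cohort(sd.alspac_like(n=2000), seed=6)
    truth = sd.ground_truth_milestones(coh, "ar")
    med = truth[truth["valid"]]["age"].median()
    pop = ms.find_adiposity_rebound(
        bmi_height_basis().curve(np.array(sd.childhood_mean_coefficients())))
    assert abs(med - pop.age) < 0.2
    assert 5.3 < med < 6.1


def test_full_determinism():
    a = sd.simulate_cohort(sd.alspac_like(n=120), seed=9)
    b = sd.simulate_cohort(sd.alspac_like(n=120), seed=9)
    assert a.growth.to_csv() == b.growth.to_csv()
    assert a.individuals.to_csv() == b.individuals.to_csv()
    np.testing.assert_array_equal(a.panel.dosages, b.panel.dosages)
    c = sd.simulate_cohort(sd.alspac_like(n=120), seed=10)
    assert a.growth.to_csv() != c.growth.to_csv()


def test_schedule_density_presets():
    dense = sd.simulate_cohort(sd.alspac_like(n=400), seed=11)
    nb = dense.growth[(dense.growth.measure == "bmi")
                      & (dense.growth.age >= 1)].groupby("individual_id").size()
    assert 8 <= nb.median() <= 10
    sparse = sd.simulate_cohort(sd.raine_like(n=400), seed=11)
    nr = sparse.growth[sparse.growth.measure == "bmi"].groupby(
        "individual_id").size()
    assert 5 <= nr.median() <= 7
    # sparse cohort has (almost) no data between 3.2 and 5.5 years
    gap = sparse.growth[(sparse.growth.age > 3.2) & (sparse.growth.age < 5.5)]
    assert len(gap) == 0


def test_parental_reports_only_in_dense_preset():
    dense = sd.simulate_cohort(sd.alspac_like(n=100), seed=12)
    sparse = sd.simulate_cohort(sd.raine_like(n=100), seed=12)
    assert (dense.growth["source"] == "parental_report").any()
    assert (sparse.growth["source"] == "parental_report").sum() == 0
    assert [c for c in sparse.individuals.columns if c.startswith("pc")] == \
        [f"pc{i}" for i in range(1, 6)]


def test_weight_coherent_with_bmi_and_height():
    coh = sd.simulate_cohort(sd.alspac_like(n=50, implausible_rate=0.0),
                             seed=13)
    g = coh.growth
    wide = g.pivot_table(index=["individual_id", "age"], columns="measure",
                         values="value").dropna()
    np.testing.assert_allclose(
        wide["weight"], wide["bmi"] * (wide["height"] / 100.0) ** 2,
        rtol=1e-9)


def test_simulate_trajectories_reuses_panel():
    panel = sd.simulate_genotypes(80, seed=21)
    params = sd.alspac_like(n=80)
    coh = sd.simulate_trajectories(panel, params, seed=22)
    assert list(coh.panel.individual_ids) == list(panel.individual_ids)
    np.testing.assert_array_equal(coh.panel.dosages, panel.dosages)
    assert set(coh.growth["individual_id"]) <= set(panel.individual_ids)
    with pytest.raises(ValueError, match="panel size"):
        sd.simulate_trajectories(panel, sd.alspac_like(n=81), seed=22)
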