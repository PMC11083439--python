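"""The forward model: determinism, identifiability, and configured contrasts."""

import dataclasses

import numpy as np
import pytest

from larvaniche.growth import DEF, MIX, OPT, fit_and_classify, fit_loglinear
from larvaniche.maternal import fit_factor_regression
from larvaniche.stats import ancova_group_effect
from larvaniche.synthetic import (
    SimulationConfig,
    default_cohort_configs,
    simulate_cohort,
    simulate_two_cohorts,
)
from larvaniche.trophic import tp_for_dataset
from tests.conftest import noise_free_config


def test_same_seed_identical_datasets():
    cfg = SimulationConfig()
    ds1, t1 = simulate_cohort(cfg, seed=123)
    ds2, t2 = simulate_cohort(cfg, seed=123)
    assert ds1.larvae == ds2.larvae
    assert ds1.stations == ds2.stations
    assert t1 == t2


def test_different_seed_differs():
    cfg = SimulationConfig()
    ds1, _ = simulate_cohort(cfg, seed=1)
    ds2, _ = simulate_cohort(cfg, seed=2)
    assert ds1.larvae != ds2.larvae


def test_noise_free_recovery_of_all_coefficients(noise_free_dataset):
    """Zero noise ⇒ growth and factor regressions return the generator values."""
    cfg, ds, _ = noise_free_dataset
    fit_sl = fit_loglinear(ds, "SL")
    assert (fit_sl.intercept, fit_sl.slope) == pytest.approx((cfg.a_sl, cfg.b_sl), abs=1e-10)
    fit_dw = fit_loglinear(ds, "DW")
    assert (fit_dw.intercept, fit_dw.slope) == pytest.approx((cfg.a_dw, cfg.b_dw), abs=1e-10)

    pre = [l for l in ds.larvae if l.stage == "PRE"]
    eggs = np.full(len(pre), cfg.maternal_d15n_mean)
    reg = fit_factor_regression(pre, eggs, "d15n")
    assert (reg.intercept, reg.slope) == pytest.approx(cfg.factor_d15n, abs=1e-10)
    eggs13 = np.full(len(pre), cfg.maternal_d13c_mean)
    reg13 = fit_factor_regression(pre, eggs13, "d13c")
    assert (reg13.intercept, reg13.slope) == pytest.approx(cfg.factor_d13c, abs=1e-10)


def test_factor_slope_recovered_within_two_se():
    """n_pre = 200 noisy larvae: fitted slope within 2 SE of the truth."""
    cfg = SimulationConfig(n_pre=200, n_post=0)
    ds, truth = simulate_cohort(cfg, seed=31)
    eggs = np.array([t.egg_d15n for t in truth])
    reg = fit_factor_regression(ds.larvae, eggs, "d15n")
    # standard error from the residual spread of the fitted line
    ages = np.array([l.age_days for l in ds.larvae], dtype=float)
    resid = (eggs - np.array([l.d15n for l in ds.larvae])) - (reg.intercept + reg.slope * ages)
    se = np.sqrt(np.sum(resid**2) / (len(ages) - 2) / np.sum((ages - ages.mean()) ** 2))
    assert abs(reg.slope - cfg.factor_d15n[1]) < 2 * se


def test_two_cohort_baseline_contrast():
    """Micro-zooplankton baselines configured 0.56 vs 3.61 ‰ differ by ≈ 3.05 ‰."""
    a, b = default_cohort_configs()
    a = dataclasses.replace(a, n_stations=50)
    b = dataclasses.replace(b, n_stations=50)
    ds, _ = simulate_two_cohorts(a, b, seed=17)
    means = {
        c: np.mean([s.d15n_micro for s in ds.stations if s.cohort == c])
        for c in ("GOM17", "GOM18")
    }
    assert means["GOM18"] - means["GOM17"] == pytest.approx(3.05, abs=0.25)


def test_colliding_cohort_labels_rejected():
    cfg = SimulationConfig()
    with pytest.raises(ValueError):
        simulate_two_cohorts(cfg, dataclasses.replace(cfg), seed=0)


def test_identical_configs_no_cohort_effect():
    """Same generating process for both labels: ANCOVA type-I rate ≈ α."""
    base = SimulationConfig(n_pre=20, n_post=20, n_stations=2)
    other = dataclasses.replace(base, cohort="GOMX")
    rejections = 0
    n_rep = 200
    for rep in range(n_rep):
        ds, _ = simulate_two_cohorts(base, other, seed=1000 + rep)
        y = np.log([l.sl_mm for l in ds.larvae])
        age = np.array([l.age_days for l in ds.larvae], dtype=float)
        grp = np.array([l.cohort for l in ds.larvae])
        rejections += ancova_group_effect(y, age, grp).p < 0.05
    assert 0.01 <= rejections / n_rep <= 0.10


def test_tp_contrast_orders_estimates():
    """TP_true 4.1 vs 3.5 produces ordered post-flexion TP estimates."""
    a, b = default_cohort_configs()
    ds, _ = simulate_two_cohorts(a, b, seed=29)
    results = {r.larva_id: r.tp for r in tp_for_dataset(ds)}
    post_tp = {
        c: np.mean(
            [results[l.larva_id] for l in ds.larvae if l.cohort == c and l.stage == "POST"]
        )
        for c in ("GOM17", "GOM18")
    }
    assert post_tp["GOM17"] > post_tp["GOM18"]


def test_growth_heterogeneity_increases_opt_def_fraction():
    """More spread in latent growth potential → fewer MIX larvae."""
    def decided_fraction(sigma_g, seeds):
        fracs = []
        for s in seeds:
            cfg = SimulationConfig(sigma_g=sigma_g, n_pre=60, n_post=60)
            ds, _ = simulate_cohort(cfg, seed=s)
            _, _, labels = fit_and_classify(ds)
            fracs.append(np.mean([l.label in (OPT, DEF) for l in labels]))
        return np.mean(fracs)

    seeds = range(50, 62)
    assert decided_fraction(0.30, seeds) > decided_fraction(0.02, seeds)


def test_cn_anticorrelated_with_growth_potential():
    cfg = SimulationConfig(n_pre=150, n_post=150)
    ds, truth = simulate_cohort(cfg, seed=19)
    g = np.array([t.g for t in truth])
    cn = np.array([l.cn for l in ds.larvae])
    assert np.corrcoef(g, cn)[0, 1] < -0.5


def test_maternal_growth_correlation_has_configured_sign():
    cfg = SimulationConfig(n_pre=400, n_post=0, rho=-0.5)
    _, truth = simulate_cohort(cfg, seed=13)
    g = np.array([t.g for t in truth])
    egg = np.array([t.egg_d15n for t in truth])
    r = np.corrcoef(g, egg)[0, 1]
    assert -0.7 < r < -0.3


def test_invalid_config_fields_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(rho=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(sigma_g=-0.1)
    with pytest.raises(ValueError):
        SimulationConfig(n_pre=-1)


def test_otolith_metrics_monotone_in_sl(noise_free_dataset):
    _, ds, _ = noise_free_dataset
    order = np.argsort([l.sl_mm for l in ds.larvae])
    radius = np.array([l.radius_um for l in ds.larvae])[order]
    miw = np.array([l.miw_um for l in ds.larvae])[order]
    assert np.all(np.diff(radius) >= 0)
    assert np.all(np.diff(miw) >= 0)
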