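"""Egg draws, (egg − larva) factor regressions, and maternal back-calculation."""

import dataclasses

import numpy as np
import pytest

from larvaniche.dataio import LarvaRecord
from larvaniche.maternal import (
    EggIsotopeParams,
    FactorRegression,
    draw_egg_values,
    estimate_maternal,
    estimate_maternal_dataset,
    fit_factor_regression,
    maternal_group_summary,
)
from larvaniche.synthetic import simulate_cohort
from tests.conftest import noise_free_config

PARAMS = EggIsotopeParams(mean_d15n_egg=12.0, sd_d15n_egg=0.5, mean_d13c_egg=-18.0, sd_d13c_egg=0.3)


def _pre_larva(lid, age, d15n, d13c=-18.5):
    return LarvaRecord(
        larva_id=lid, cohort="C", station_id="S", age_days=age, sl_mm=5.0, dw_mg=0.3,
        radius_um=20.0, miw_um=1.5, stage="PRE", d15n=d15n, d13c=d13c, cn=3.5,
    )


def test_zero_sd_draws_equal_mean():
    p = EggIsotopeParams(12.0, 0.0, -18.0, 0.0)
    d15n, d13c = draw_egg_values(p, 5, seed=1)
    assert np.all(d15n == 12.0) and np.all(d13c == -18.0)


def test_draws_deterministic_and_clt_bound():
    a15, a13 = draw_egg_values(PARAMS, 10000, seed=9)
    b15, b13 = draw_egg_values(PARAMS, 10000, seed=9)
    assert np.array_equal(a15, b15) and np.array_equal(a13, b13)
    # 4σ/√n band around the mean
    assert abs(a15.mean() - 12.0) < 0.02
    assert abs(a13.mean() - (-18.0)) < 0.012


def test_negative_sd_rejected():
    with pytest.raises(ValueError):
        EggIsotopeParams(12.0, -0.1, -18.0, 0.0)


def test_factor_regression_recovers_noise_free_coefficients():
    """Larvae built as larva = egg − (0.975 + 0.527·age) regress back exactly."""
    c0, c1 = 0.975, 0.527
    egg = 12.0
    larvae = [_pre_larva(f"L{i}", age, egg - (c0 + c1 * age)) for i, age in enumerate(range(5, 16))]
    reg = fit_factor_regression(larvae, np.full(len(larvae), egg), "d15n")
    assert reg.intercept == pytest.approx(c0, abs=1e-10)
    assert reg.slope == pytest.approx(c1, abs=1e-10)
    assert reg.r2 == pytest.approx(1.0, abs=1e-10)


def test_factor_regression_age_independent_gives_zero_slope():
    larvae = [_pre_larva(f"L{i}", age, 5.0) for i, age in enumerate([5, 8, 11, 14])]
    reg = fit_factor_regression(larvae, np.full(4, 12.0), "d15n")
    assert reg.slope == pytest.approx(0.0, abs=1e-12)


def test_factor_regression_matches_ols_oracle(rng):
    for _ in range(50):
        n = int(rng.integers(5, 30))
        ages = rng.integers(5, 16, n)
        if np.ptp(ages) == 0:
            continue
        vals = rng.normal(5, 1, n)
        eggs = rng.normal(12, 0.5, n)
        larvae = [_pre_larva(f"L{i}", int(a), float(v)) for i, (a, v) in enumerate(zip(ages, vals))]
        reg = fit_factor_regression(larvae, eggs, "d15n")
        x = np.column_stack([np.ones(n), ages.astype(float)])
        beta = np.linalg.solve(x.T @ x, x.T @ (eggs - vals))
        assert reg.intercept == pytest.approx(beta[0], abs=1e-8)
        assert reg.slope == pytest.approx(beta[1], abs=1e-8)


def test_factor_regression_preconditions():
    larvae = [_pre_larva(f"L{i}", 7, 5.0) for i in range(5)]
    with pytest.raises(ValueError):
        fit_factor_regression(larvae, np.full(5, 12.0), "d15n")  # all ages equal
    post = dataclasses.replace(larvae[0], stage="POST")
    with pytest.raises(ValueError):
        fit_factor_regression([post] * 3, np.full(3, 12.0), "d15n")


def test_estimate_maternal_hand_value():
    """δ15N 5.0 at age 10 with factor (0.975, 0.527) → 5.0 + 0.975 + 5.27."""
    reg = FactorRegression(isotope="d15n", intercept=0.975, slope=0.527,
                           p_value=0.001, r2=0.52, n=52, age_min=5, age_max=15)
    larva = _pre_larva("L1", 10, 5.0)
    assert estimate_maternal(larva, reg) == pytest.approx(11.245, abs=1e-12)


def test_estimate_constant_factor_shifts_by_k():
    reg = FactorRegression(isotope="d15n", intercept=2.5, slope=0.0,
                           p_value=0.5, r2=0.0, n=10, age_min=1, age_max=100)
    for age in (5, 10, 25):
        larva = _pre_larva("L1", age, 6.0)
        assert estimate_maternal(larva, reg) == pytest.approx(8.5)


def test_estimate_warns_on_extrapolation():
    reg = FactorRegression(isotope="d15n", intercept=1.0, slope=0.5,
                           p_value=0.01, r2=0.5, n=10, age_min=5, age_max=15)
    with pytest.warns(UserWarning, match="extrapolating"):
        estimate_maternal(_pre_larva("L1", 20, 5.0), reg)


def test_noise_free_estimates_equal_egg_values(noise_free_dataset):
    """sd_egg = 0 and exact forward model ⇒ every estimate equals the egg value."""
    cfg, ds, truth = noise_free_dataset
    pre = [l for l in ds.larvae if l.stage == "PRE"]
    eggs = np.full(len(pre), cfg.maternal_d15n_mean)
    eggs13 = np.full(len(pre), cfg.maternal_d13c_mean)
    reg15 = fit_factor_regression(pre, eggs, "d15n")
    reg13 = fit_factor_regression(pre, eggs13, "d13c")
    for est in estimate_maternal_dataset(pre, reg15, reg13):
        assert est.d15n_maternal == pytest.approx(cfg.maternal_d15n_mean, abs=1e-9)
        assert est.d13c_maternal == pytest.approx(cfg.maternal_d13c_mean, abs=1e-9)


def test_estimator_is_linear_in_scale():
    """Scaling larval values and egg means by λ scales estimates by λ."""
    lam = 2.5
    ages = list(range(5, 16))
    vals = [5.0 + 0.1 * a for a in ages]
    eggs = np.linspace(11.5, 12.5, len(ages))
    larvae = [_pre_larva(f"L{i}", a, v) for i, (a, v) in enumerate(zip(ages, vals))]
    scaled = [dataclasses.replace(l, d15n=lam * l.d15n) for l in larvae]
    reg = fit_factor_regression(larvae, eggs, "d15n")
    reg_s = fit_factor_regression(scaled, lam * eggs, "d15n")
    for l, ls in zip(larvae, scaled):
        assert estimate_maternal(ls, reg_s) == pytest.approx(lam * estimate_maternal(l, reg), rel=1e-10)


def test_noisy_recovery_of_maternal_mean():
    """n = 50 pre-flexion larvae, 0.3 ‰ noise: mean estimate within ±0.2 ‰."""
    cfg = noise_free_config(n_pre=50, n_post=0, sigma_iso=0.3, maternal_d15n_sd=0.5,
                            maternal_d13c_sd=0.3)
    ds, truth = simulate_cohort(cfg, seed=21)
    pre = ds.larvae
    eggs15 = np.full(len(pre), cfg.maternal_d15n_mean)
    eggs13 = np.full(len(pre), cfg.maternal_d13c_mean)
    reg15 = fit_factor_regression(pre, eggs15, "d15n")
    reg13 = fit_factor_regression(pre, eggs13, "d13c")
    ests = estimate_maternal_dataset(pre, reg15, reg13)
    mean15 = np.mean([e.d15n_maternal for e in ests])
    assert abs(mean15 - cfg.maternal_d15n_mean) < 0.2


def test_group_summary_matches_brute_force():
    ests = estimate_maternal_dataset(
        [_pre_larva(f"L{i}", a, 5.0 + 0.1 * i) for i, a in enumerate([5, 7, 9, 11])],
        FactorRegression("d15n", 1.0, 0.5, 0.01, 0.5, 4, 5, 11),
        FactorRegression("d13c", 0.5, -0.1, 0.01, 0.5, 4, 5, 11),
    )
    grouping = {"L0": "A", "L1": "A", "L2": "B", "L3": "B"}
    out = maternal_group_summary(ests, grouping)
    for group in ("A", "B"):
        vals = [e.d15n_maternal for e in ests if grouping[e.larva_id] == group]
        row = out[(out.group == group) & (out.isotope == "d15n_maternal")].iloc[0]
        assert row["mean"] == pytest.approx(np.mean(vals))
        assert row["sd"] == pytest.approx(np.std(vals, ddof=1))
        assert row["n"] == 2


def test_group_summary_constant_groups_zero_sd():
    from larvaniche.maternal import MaternalEstimate

    ests = [
        MaternalEstimate("L1", 12.0, -18.0),
        MaternalEstimate("L2", 12.0, -18.0),
        MaternalEstimate("L3", 13.0, -17.5),
        MaternalEstimate("L4", 13.0, -17.5),
    ]
    grouping = {"L1": "A", "L2": "A", "L3": "B", "L4": "B"}
    out = maternal_group_summary(ests, grouping)
    assert (out["sd"] == 0.0).all()


def test_group_summary_requires_two_per_group():
    from larvaniche.maternal import MaternalEstimate

    ests = [MaternalEstimate("L1", 12.0, -18.0), MaternalEstimate("L2", 12.5, -18.0)]
    with pytest.raises(ValueError):
        maternal_group_summary(ests, {"L1": "A", "L2": "B"})


def test_def_maternal_exceeds_opt_across_replicates():
    """When DEF eggs are 0.8 ‰ enriched, the estimated DEF mean exceeds OPT
    in at least 95 % of replicates."""
    rng = np.random.default_rng(77)
    wins = 0
    n_rep = 200
    for _ in range(n_rep):
        ages = rng.integers(5, 16, 50)
        while np.ptp(ages) == 0:
            ages = rng.integers(5, 16, 50)
        group = np.array(["OPT"] * 25 + ["DEF"] * 25)
        egg_mean = np.where(group == "DEF", 12.8, 12.0)
        eggs = egg_mean + 0.3 * rng.standard_normal(50)
        vals = eggs - (1.0 + 0.5 * ages) + 0.3 * rng.standard_normal(50)
        larvae = [_pre_larva(f"L{i}", int(a), float(v)) for i, (a, v) in enumerate(zip(ages, vals))]
        reg15 = fit_factor_regression(larvae, eggs, "d15n")
        reg13 = FactorRegression("d13c", 0.0, 0.0, 1.0, 0.0, 50, 5, 15)
        ests = estimate_maternal_dataset(larvae, reg15, reg13)
        m = {
            g: np.mean([e.d15n_maternal for e, gg in zip(ests, group) if gg == g])
            for g in ("OPT", "DEF")
        }
        wins += m["DEF"] > m["OPT"]
    assert wins / n_rep >= 0.95
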