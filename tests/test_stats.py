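"""Mann–Whitney Z, ANCOVA, ANOVA and the test-selection rule."""

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings, strategies as st

from larvaniche.stats import (
    ancova_group_effect,
    anova_group_effect,
    mann_whitney_z,
    select_test,
)


def test_mann_whitney_worked_example():
    """a = [1,2,3], b = [4,5,6]: U = 0, Z = −4.5/√5.25 ≈ −1.964."""
    res = mann_whitney_z([1, 2, 3], [4, 5, 6])
    assert res.u == 0.0
    assert res.statistic == pytest.approx(-4.5 / np.sqrt(5.25), abs=1e-12)
    assert res.statistic == pytest.approx(-1.964, abs=5e-4)


def test_mann_whitney_symmetric_samples_give_zero_z():
    res = mann_whitney_z([1, 2, 3], [1, 2, 3])
    assert abs(res.statistic) < 1e-12


def test_mann_whitney_degenerate_pooled_sample():
    with pytest.raises(ValueError):
        mann_whitney_z([2, 2], [2, 2, 2])


@given(
    a=st.lists(st.integers(0, 50), min_size=1, max_size=12),
    b=st.lists(st.integers(0, 50), min_size=1, max_size=12),
)
@settings(derandomize=True, max_examples=80)
def test_mann_whitney_u_plus_uprime(a, b):
    """U + U′ = n_a·n_b, with and without ties."""
    if np.ptp(a + b) == 0:
        return
    u_a = mann_whitney_z(a, b).u
    u_b = mann_whitney_z(b, a).u
    assert u_a + u_b == pytest.approx(len(a) * len(b), abs=1e-9)


def test_mann_whitney_sign_antisymmetric(rng):
    a = rng.normal(0, 1, 9)
    b = rng.normal(1, 1, 7)
    ab = mann_whitney_z(a, b)
    ba = mann_whitney_z(b, a)
    assert ab.statistic == pytest.approx(-ba.statistic, abs=1e-10)
    assert ab.p == pytest.approx(ba.p, abs=1e-12)


def test_mann_whitney_matches_scipy_with_ties(rng):
    """Tie-corrected p agrees with scipy's asymptotic implementation."""
    for _ in range(20):
        a = rng.integers(0, 6, rng.integers(5, 15)).astype(float)
        b = rng.integers(0, 6, rng.integers(5, 15)).astype(float)
        if np.ptp(np.concatenate([a, b])) == 0:
            continue
        ours = mann_whitney_z(a, b, continuity=True)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-9)


def _brute_force_ancova_f(y, age, indicator):
    x_full = np.column_stack([np.ones_like(age), age, indicator])
    x_red = x_full[:, :2]
    rss = lambda x: np.sum((y - x @ np.linalg.lstsq(x, y, rcond=None)[0]) ** 2)
    rss_full, rss_red = rss(x_full), rss(x_red)
    return (rss_red - rss_full) / (rss_full / (len(y) - 3))


def test_ancova_matches_nested_model_oracle(rng):
    for _ in range(50):
        n = int(rng.integers(10, 60))
        age = rng.integers(5, 30, n).astype(float)
        group = rng.permutation(np.array(["A"] * (n // 2) + ["B"] * (n - n // 2)))
        if min(np.ptp(age[group == g]) for g in "AB") == 0:
            continue
        y = 1.0 + 0.1 * age + 0.3 * (group == "B") + rng.normal(0, 0.5, n)
        res = ancova_group_effect(y, age, group)
        f_ref = _brute_force_ancova_f(y, age, (group == "B").astype(float))
        assert abs(res.statistic - f_ref) < 1e-8
        assert res.df == (1, n - 3)


def test_ancova_identical_groups_f_near_zero(rng):
    age = np.tile(np.arange(5, 20, dtype=float), 2)
    y = 1.0 + 0.05 * age  # identical in values, no group signal, no noise
    group = np.array(["A"] * 15 + ["B"] * 15)
    res = ancova_group_effect(y, age, group)
    assert res.statistic == pytest.approx(0.0, abs=1e-8)


def test_ancova_confounded_design_rejected():
    y = np.arange(10, dtype=float)
    age = np.array([5.0] * 5 + list(range(5)))
    group = np.array(["A"] * 5 + ["B"] * 5)
    with pytest.raises(ValueError):
        ancova_group_effect(y, age, group)  # age constant within group A


def test_ancova_invariant_to_affine_rescaling(rng):
    n = 40
    age = rng.integers(5, 30, n).astype(float)
    group = np.array(["A"] * 20 + ["B"] * 20)
    y = 0.5 + 0.02 * age + 0.1 * (group == "B") + rng.normal(0, 0.2, n)
    f0 = ancova_group_effect(y, age, group).statistic
    f1 = ancova_group_effect(3.0 * y - 7.0, 0.5 * age + 11.0, group).statistic
    assert f1 == pytest.approx(f0, rel=1e-9)


def test_anova_matches_hand_computed_table():
    """Two groups of three: F computed from first principles."""
    a = np.array([1.0, 2.0, 3.0])
    b = np.array([2.0, 3.0, 4.0])
    grand = np.concatenate([a, b]).mean()
    ss_between = 3 * ((a.mean() - grand) ** 2 + (b.mean() - grand) ** 2)
    ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    f_hand = (ss_between / 1) / (ss_within / 4)
    res = anova_group_effect(np.concatenate([a, b]), np.array(["A"] * 3 + ["B"] * 3))
    assert res.statistic == pytest.approx(f_hand, rel=1e-12)
    assert res.df == (1, 4)


def test_anova_identical_groups():
    y = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
    res = anova_group_effect(y, np.array(["A"] * 3 + ["B"] * 3))
    assert res.statistic == pytest.approx(0.0, abs=1e-12)


def test_anova_null_f_near_one_in_expectation(rng):
    fs = []
    for _ in range(300):
        y = rng.normal(0, 1, 24)
        fs.append(anova_group_effect(y, np.repeat(["A", "B", "C"], 8)).statistic)
    # E[F] = d2/(d2−2) = 21/19 ≈ 1.105 under the null
    assert np.mean(fs) == pytest.approx(21 / 19, abs=0.25)


def test_select_test_chooses_ancova_on_strong_trend(rng):
    age = rng.integers(5, 30, 40).astype(float)
    group = np.array(["A"] * 20 + ["B"] * 20)
    y = 2.0 + 0.2 * age + rng.normal(0, 0.1, 40)
    assert select_test(y, age, group).test == "ancova"


def test_select_test_prefers_anova_under_null(rng):
    """Age-independent response → ANOVA in ≈ 95 % of null replicates."""
    chosen = []
    for _ in range(200):
        age = rng.integers(5, 30, 30).astype(float)
        group = np.array(["A"] * 15 + ["B"] * 15)
        y = rng.normal(0, 1, 30)
        chosen.append(select_test(y, age, group).test)
    assert chosen.count("anova") / len(chosen) >= 0.90


def test_select_test_choice_deterministic(rng):
    age = rng.integers(5, 30, 30).astype(float)
    group = np.array(["A"] * 15 + ["B"] * 15)
    y = rng.normal(0, 1, 30)
    first = select_test(y, age, group).test
    assert all(select_test(y, age, group).test == first for _ in range(3))


def test_p_values_in_unit_interval(rng):
    for _ in range(20):
        a = rng.normal(0, 1, 10)
        b = rng.normal(0.5, 1, 12)
        assert 0.0 <= mann_whitney_z(a, b).p <= 1.0
        age = rng.integers(5, 30, 22).astype(float)
        assert 0.0 <= ancova_group_effect(np.concatenate([a, b]), age,
                                          np.array(["A"] * 10 + ["B"] * 12)).p <= 1.0
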