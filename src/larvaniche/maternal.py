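"""Maternal isotopic signatures back-calculated from pre-flexion larvae.

Pre-flexion larvae still carry the isotopic signal transmitted by the
spawning female through the egg; that signal decays with age as exogenous
feeding takes over.  The maternal value of each larva is reconstructed by
adding to the larval bulk value an age-regressed (egg − larva) factor:

    factor(age) = c0 + c1 · age       (OLS of egg_i − larva_i on age)
    maternal_i  = larva_i + factor(age_i)

Egg values are stochastic: one draw per larva from the Normal(mean, sd) of
egg/lecithotrophic-larvae rearing measurements.  The egg mean and sd are
required inputs — no literature constants are baked in.  The regression is
used even when its slope is non-significant; significance is reported, not
gated on.

Note the defining identity collapses algebraically to maternal = egg when
the same larva value appears in both terms; the operational estimator keeps
the two roles distinct — a *fitted* age trend of the factor, applied to each
larva's measured value — which is what gives per-larva maternal estimates
with real variance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dataio import LarvaRecord, STAGE_PRE

ISOTOPES = ("d15n", "d13c")


@dataclass
class EggIsotopeParams:
    """Mean and sd of egg / lecithotrophic-larvae isotope values (‰)."""

    mean_d15n_egg: float
    sd_d15n_egg: float
    mean_d13c_egg: float
    sd_d13c_egg: float

    def __post_init__(self) -> None:
        if self.sd_d15n_egg < 0 or self.sd_d13c_egg < 0:
            raise ValueError("egg isotope sds must be >= 0")


@dataclass
class FactorRegression:
    """OLS of the (egg − larva) factor on age for one isotope."""

    isotope: str
    intercept: float  # c0
    slope: float  # c1, per day
    p_value: float
    r2: float
    n: int
    age_min: int = 0
    age_max: int = 10**9

    def factor(self, age_days: float) -> float:
        return self.intercept + self.slope * age_days


@dataclass
class MaternalEstimate:
    larva_id: str
    d15n_maternal: float
    d13c_maternal: float


def draw_egg_values(
    params: EggIsotopeParams, n: int, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray]:
    """``n`` paired (δ15N_egg, δ13C_egg) draws; independent normals per isotope."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d15n = params.mean_d15n_egg + params.sd_d15n_egg * rng.standard_normal(n)
    d13c = params.mean_d13c_egg + params.sd_d13c_egg * rng.standard_normal(n)
    return d15n, d13c


def fit_factor_regression(
    pre_larvae: list[LarvaRecord], egg_values: np.ndarray, isotope: str
) -> FactorRegression:
    """Regress (egg_i − larva_i) on age over pre-flexion larvae.

    ``egg_values`` holds one egg draw per larva, aligned with ``pre_larvae``
    (use the egg mean for every larva for a deterministic expected-value fit).
    """
    if isotope not in ISOTOPES:
        raise ValueError(f"isotope must be one of {ISOTOPES}, got {isotope!r}")
    if len(pre_larvae) < 3:
        raise ValueError(f"need >= 3 pre-flexion larvae, got {len(pre_larvae)}")
    if any(l.stage != STAGE_PRE for l in pre_larvae):
        raise ValueError("all larvae must be stage PRE")
    egg_values = np.asarray(egg_values, dtype=float)
    if len(egg_values) != len(pre_larvae):
        raise ValueError("need exactly one egg value per larva")

    larva_vals = np.array([getattr(l, isotope) for l in pre_larvae], dtype=float)
    age = np.array([l.age_days for l in pre_larvae], dtype=float)
    if np.ptp(age) == 0:
        raise ValueError("degenerate design: all ages equal")

    factor = egg_values - larva_vals
    res = sm.OLS(factor, sm.add_constant(age)).fit()
    return FactorRegression(
        isotope=isotope,
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        p_value=float(res.pvalues[1]),
        r2=float(res.rsquared) if np.var(factor) > 0 else 0.0,
        n=len(pre_larvae),
        age_min=int(age.min()),
        age_max=int(age.max()),
    )


def estimate_maternal(larva: LarvaRecord, reg: FactorRegression) -> float:
    """Maternal value (‰) for one isotope: larva value + age-predicted factor.

    Ages outside the fitted range are extrapolated with a warning.
    """
    if not (reg.age_min <= larva.age_days <= reg.age_max):
        warnings.warn(
            f"larva {larva.larva_id}: age {larva.age_days} d outside fitted "
            f"range [{reg.age_min}, {reg.age_max}]; extrapolating",
            stacklevel=2,
        )
    return getattr(larva, reg.isotope) + reg.factor(larva.age_days)


def estimate_maternal_dataset(
    pre_larvae: list[LarvaRecord],
    reg_d15n: FactorRegression,
    reg_d13c: FactorRegression,
) -> list[MaternalEstimate]:
    """Per-larva maternal (δ15N, δ13C) estimates for a pre-flexion group."""
    out = []
    for larva in pre_larvae:
        est = MaternalEstimate(
            larva_id=larva.larva_id,
            d15n_maternal=estimate_maternal(larva, reg_d15n),
            d13c_maternal=estimate_maternal(larva, reg_d13c),
        )
        if not (math.isfinite(est.d15n_maternal) and math.isfinite(est.d13c_maternal)):
            raise ValueError(f"non-finite maternal estimate for {larva.larva_id}")
        out.append(est)
    return out


def maternal_group_summary(
    estimates: list[MaternalEstimate], grouping: dict[str, str]
) -> pd.DataFrame:
    """Mean ± sd of maternal values per group.

    ``grouping`` maps larva_id -> group label (cohort, or OPT/DEF class).
    Returns one row per (group, isotope) with mean, sd (ddof=1) and n;
    every group needs at least 2 members.
    """
    rows = []
    for est in estimates:
        if est.larva_id not in grouping:
            continue
        rows.append(
            {
                "group": grouping[est.larva_id],
                "d15n_maternal": est.d15n_maternal,
                "d13c_maternal": est.d13c_maternal,
            }
        )
    if not rows:
        raise ValueError("no estimates matched the grouping")
    df = pd.DataFrame(rows)
    counts = df.groupby("group").size()
    small = counts[counts < 2]
    if not small.empty:
        raise ValueError(f"groups with < 2 estimates: {list(small.index)}")
    long = df.melt(id_vars="group", var_name="isotope", value_name="value")
    out = (
        long.groupby(["group", "isotope"])["value"]
        .agg(mean="mean", sd="std", n="size")
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out
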