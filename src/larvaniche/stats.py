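"""Group-comparison tests: Mann–Whitney U (Z-adjusted), ANCOVA, ANOVA.

The Mann–Whitney Z statistic is the tie-corrected normal approximation

    U  = R_a − n_a(n_a+1)/2            (rank sum of the first sample)
    Z  = (U − n_a n_b / 2) / σ_U,
    σ²_U = n_a n_b / 12 · [ (n + 1) − Σ(t³ − t) / (n (n − 1)) ],

with midranks for ties; a continuity correction is available but off by
default (matching the "Z-adjusted" convention of common statistics
packages).  Group contrasts of age-dependent variables use ANCOVA
(y ~ age + group, Type-II F for the group term); age-independent variables
fall back to one-way ANOVA, chosen automatically by ``select_test``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps


@dataclass
class GroupStats:
    mean: float
    sd: float
    n: int


@dataclass
class TestResult:
    test: str  # "mann-whitney", "ancova", "anova"
    statistic: float  # Z for MW, F otherwise
    p: float
    u: float | None = None
    df: tuple[int, int] | None = None
    groups: dict[str, GroupStats] = field(default_factory=dict)

    @property
    def stars(self) -> str:
        """Significance stars as printed in field tables (α 0.05 / 0.01)."""
        if self.p < 0.01:
            return "**"
        if self.p < 0.05:
            return "*"
        return "NS"


def _group_stats(values: dict[str, np.ndarray]) -> dict[str, GroupStats]:
    out = {}
    for label, v in values.items():
        v = np.asarray(v, dtype=float)
        out[label] = GroupStats(
            mean=float(v.mean()),
            sd=float(v.std(ddof=1)) if len(v) > 1 else float("nan"),
            n=len(v),
        )
    return out


def mann_whitney_z(a, b, continuity: bool = False, labels: tuple[str, str] = ("a", "b")) -> TestResult:
    """Tie-corrected Mann–Whitney U with normal-approximation Z and p.

    U is reported for the first sample; Z < 0 means the first sample ranks
    lower.  Raises when the pooled sample has zero variance (all values
    identical), since ranks are then uninformative.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = len(a), len(b)
    if n_a < 1 or n_b < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        raise ValueError("all pooled values identical; ranks are degenerate")

    ranks = sps.rankdata(pooled)  # midranks for ties
    r_a = ranks[:n_a].sum()
    u = r_a - n_a * (n_a + 1) / 2.0
    n = n_a + n_b
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
    var_u = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    mean_u = n_a * n_b / 2.0
    diff = u - mean_u
    if continuity:
        diff = math.copysign(max(abs(diff) - 0.5, 0.0), diff)
    z = diff / math.sqrt(var_u)
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(
        test="mann-whitney",
        statistic=float(z),
        p=float(min(p, 1.0)),
        u=float(u),
        groups=_group_stats({labels[0]: a, labels[1]: b}),
    )


def _two_level(group) -> tuple[np.ndarray, list[str]]:
    group = np.asarray(group)
    levels = sorted(set(group.tolist()))
    if len(levels) != 2:
        raise ValueError(f"group must have exactly 2 levels, got {levels}")
    return (group == levels[1]).astype(float), [str(l) for l in levels]


def ancova_group_effect(y, age, group, log_transform: bool = False) -> TestResult:
    """F test for a 2-level group effect controlling for age.

    Fits y ~ age + group by OLS and reports the Type-II partial F for the
    group term with df (1, n − 3).  ``log_transform`` takes the natural log
    of y first (y must then be positive).
    """
    y = np.asarray(y, dtype=float)
    age = np.asarray(age, dtype=float)
    indicator, levels = _two_level(group)
    group = np.asarray(group)
    n = len(y)
    if not (len(age) == len(indicator) == n):
        raise ValueError("y, age, group must have equal length")
    for lev in levels:
        mask = group.astype(str) == lev
        if mask.sum() < 3:
            raise ValueError(f"need >= 3 observations in group {lev!r}")
        if np.ptp(age[mask]) == 0:
            raise ValueError(f"age constant within group {lev!r}: confounded design")
    if log_transform:
        if np.any(y <= 0):
            raise ValueError("log transform requires positive y")
        y = np.log(y)

    x_full = sm.add_constant(np.column_stack([age, indicator]))
    x_red = sm.add_constant(age)
    full = sm.OLS(y, x_full).fit()
    red = sm.OLS(y, x_red).fit()
    df_denom = n - 3
    rss_full = float(full.ssr)
    rss_red = float(red.ssr)
    if rss_full <= 0:
        f_stat, p = 0.0, 1.0
    else:
        f_stat = (rss_red - rss_full) / (rss_full / df_denom)
        f_stat = max(f_stat, 0.0)
        p = float(sps.f.sf(f_stat, 1, df_denom))
    return TestResult(
        test="ancova",
        statistic=float(f_stat),
        p=p,
        df=(1, df_denom),
        groups=_group_stats({lev: y[group.astype(str) == lev] for lev in levels}),
    )


def anova_group_effect(y, group) -> TestResult:
    """One-way ANOVA F for any number of groups."""
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    levels = sorted(set(group.astype(str).tolist()))
    samples = [y[group.astype(str) == lev] for lev in levels]
    if any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 observations per group")
    if all(np.ptp(s) == 0 for s in samples):
        raise ValueError("zero within-group variance in every group")
    f_stat, p = sps.f_oneway(*samples)
    n = len(y)
    k = len(levels)
    return TestResult(
        test="anova",
        statistic=float(f_stat),
        p=float(p),
        df=(k - 1, n - k),
        groups=_group_stats(dict(zip(levels, samples))),
    )


def select_test(y, age, group, alpha: float = 0.05, log_transform: bool = False) -> TestResult:
    """ANCOVA when y depends linearly on age (slope significant at α), else ANOVA.

    The choice is a deterministic function of the age-slope p-value from the
    OLS fit y ~ age; the chosen test's name is in the returned result.
    """
    y_t = np.asarray(y, dtype=float)
    if log_transform:
        if np.any(y_t <= 0):
            raise ValueError("log transform requires positive y")
        y_t = np.log(y_t)
    age = np.asarray(age, dtype=float)
    slope_fit = sm.OLS(y_t, sm.add_constant(age)).fit()
    if float(slope_fit.pvalues[1]) < alpha:
        return ancova_group_effect(y_t, age, group, log_transform=False)
    return anova_group_effect(y_t, group)
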