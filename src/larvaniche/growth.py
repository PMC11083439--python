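"""Log-linear growth fits and residual-based OPT/DEF/MIX classification.

Daily growth pattern is summarised by ordinary least squares of
log(SL) and log(DW) on age (days).  Each larva's signed residuals against
the pooled-population fits classify it as OPT (longer *and* heavier than
expected for its age: both residuals positive), DEF (both negative), or MIX
(discordant signs, dropped from OPT/DEF contrasts).  Exact-zero residuals
fall in MIX so neither extreme group is inflated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .dataio import CohortDataset, LarvaRecord

OPT = "OPT"
DEF = "DEF"
MIX = "MIX"

LOG_BASES = {"natural": math.e, "base10": 10.0}


@dataclass
class GrowthFit:
    """OLS fit of log(response) on age, with per-larva residuals."""

    response: str  # "SL" or "DW"
    log_base: str  # "natural" or "base10"
    intercept: float
    slope: float
    r2: float
    n: int
    resid_sd: float
    scope: str  # "pooled" or "per_cohort"
    residuals: dict[str, float] = field(default_factory=dict, repr=False)

    def predict(self, age_days: float) -> float:
        """Predicted log(response) at a given age."""
        return self.intercept + self.slope * age_days


@dataclass
class GrowthLabel:
    larva_id: str
    label: str
    res_sl: float
    res_dw: float


_RESPONSE_FIELD = {"SL": "sl_mm", "DW": "dw_mg"}


def fit_loglinear(
    larvae: list[LarvaRecord] | CohortDataset,
    response: str = "SL",
    log_base: str = "natural",
    scope: str = "pooled",
) -> GrowthFit:
    """OLS of log(SL or DW) on age over the given larvae.

    Requires at least 3 larvae and at least 2 distinct ages.
    """
    if isinstance(larvae, CohortDataset):
        larvae = larvae.larvae
    if response not in _RESPONSE_FIELD:
        raise ValueError(f"response must be SL or DW, got {response!r}")
    if log_base not in LOG_BASES:
        raise ValueError(f"log_base must be one of {sorted(LOG_BASES)}")
    if len(larvae) < 3:
        raise ValueError(f"need >= 3 larvae, got {len(larvae)}")

    attr = _RESPONSE_FIELD[response]
    y = np.array([getattr(l, attr) for l in larvae], dtype=float)
    if np.any(y <= 0):
        raise ValueError(f"{response} values must be positive for the log transform")
    y = np.log(y) / math.log(LOG_BASES[log_base])
    age = np.array([l.age_days for l in larvae], dtype=float)
    if np.ptp(age) == 0:
        raise ValueError("degenerate design: all ages equal")

    res = sm.OLS(y, sm.add_constant(age)).fit()
    resid = np.asarray(res.resid)
    r2 = float(res.rsquared) if np.var(y) > 0 else 0.0
    return GrowthFit(
        response=response,
        log_base=log_base,
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        r2=r2,
        n=len(larvae),
        resid_sd=float(np.std(resid, ddof=2)) if len(larvae) > 2 else 0.0,
        scope=scope,
        residuals={l.larva_id: float(r) for l, r in zip(larvae, resid)},
    )


def classify_growth(res_sl: float, res_dw: float) -> str:
    """OPT / DEF / MIX from the signs of the two residuals."""
    if not (math.isfinite(res_sl) and math.isfinite(res_dw)):
        raise ValueError(f"non-finite residual: ({res_sl}, {res_dw})")
    if res_sl > 0 and res_dw > 0:
        return OPT
    if res_sl < 0 and res_dw < 0:
        return DEF
    return MIX


def classify_cohorts(
    dataset: CohortDataset,
    fit_sl: GrowthFit | dict[str, GrowthFit],
    fit_dw: GrowthFit | dict[str, GrowthFit],
) -> list[GrowthLabel]:
    """One :class:`GrowthLabel` per larva from precomputed fits.

    ``fit_sl``/``fit_dw`` are either pooled fits or per-cohort dicts
    (cohort label -> fit), matching the fitting scope used.
    """
    labels = []
    for larva in dataset.larvae:
        fsl = fit_sl[larva.cohort] if isinstance(fit_sl, dict) else fit_sl
        fdw = fit_dw[larva.cohort] if isinstance(fit_dw, dict) else fit_dw
        try:
            res_sl = fsl.residuals[larva.larva_id]
            res_dw = fdw.residuals[larva.larva_id]
        except KeyError as exc:
            raise KeyError(f"larva {larva.larva_id} missing from growth fit") from exc
        labels.append(
            GrowthLabel(
                larva_id=larva.larva_id,
                label=classify_growth(res_sl, res_dw),
                res_sl=res_sl,
                res_dw=res_dw,
            )
        )
    return labels


def fit_and_classify(
    dataset: CohortDataset, log_base: str = "natural", scope: str = "pooled"
) -> tuple[GrowthFit | dict, GrowthFit | dict, list[GrowthLabel]]:
    """Fit SL and DW growth at the requested scope and label every larva.

    ``scope="pooled"`` fits one line per response across all cohorts (the
    default: residuals are taken with respect to the whole population);
    ``scope="per_cohort"`` fits each cohort separately, for sensitivity
    analysis.
    """
    if scope == "pooled":
        fit_sl = fit_loglinear(dataset, "SL", log_base, scope)
        fit_dw = fit_loglinear(dataset, "DW", log_base, scope)
    elif scope == "per_cohort":
        fit_sl = {
            c: fit_loglinear(dataset.subset(cohort=c), "SL", log_base, scope)
            for c in dataset.cohorts()
        }
        fit_dw = {
            c: fit_loglinear(dataset.subset(cohort=c), "DW", log_base, scope)
            for c in dataset.cohorts()
        }
    else:
        raise ValueError(f"scope must be 'pooled' or 'per_cohort', got {scope!r}")
    return fit_sl, fit_dw, classify_cohorts(dataset, fit_sl, fit_dw)
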