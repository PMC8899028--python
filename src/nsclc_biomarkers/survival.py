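"""Biomarker-stratified progression-free survival.

Stratification follows the top-half rule: samples ranked by infiltrate
density, the top ceil(n/2) labeled high. Estimation and testing use the
standard machinery — Kaplan-Meier product-limit curves, the two-group
log-rank test, and univariate Cox proportional-hazards models (Efron tie
handling) — via lifelines, surfaced through a small typed API. Times are in
months throughout.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from statsmodels.duration.hazard_regression import PHReg
from pydantic import BaseModel, Field, model_validator

logger = logging.getLogger(__name__)


class SurvivalRecord(BaseModel):
    sample_id: str
    time_months: float = Field(ge=0.0)
    event: bool
    strata: dict[str, str] = Field(default_factory=dict)


class KMCurve(BaseModel):
    """Product-limit survival curve evaluated at the distinct event times."""

    event_times: list[float]
    survival_probs: list[float]
    at_risk: list[int]

    @model_validator(mode="after")
    def _shape_and_monotonicity(self) -> "KMCurve":
        if not (len(self.event_times) == len(self.survival_probs) == len(self.at_risk)):
            raise ValueError("event_times, survival_probs, at_risk must align")
        if any(t2 <= t1 for t1, t2 in zip(self.event_times, self.event_times[1:])):
            raise ValueError("event_times must be strictly increasing")
        if any(not 0.0 <= s <= 1.0 for s in self.survival_probs):
            raise ValueError("survival probabilities must lie in [0, 1]")
        if any(s2 > s1 + 1e-12 for s1, s2 in zip(self.survival_probs, self.survival_probs[1:])):
            raise ValueError("survival probabilities must be non-increasing")
        return self

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); S = 1 before the first event."""
        s = 1.0
        for et, sp in zip(self.event_times, self.survival_probs):
            if et <= t:
                s = sp
            else:
                break
        return s


def median_split(values: Mapping[str, float]) -> dict[str, str]:
    """Label the top half of samples by density as 'high', the rest 'low'.

    Samples are sorted by descending density; the top ceil(n/2) are high.
    Ties at the boundary are broken by ascending sample id (logged).
    """
    if len(values) < 2:
        raise ValueError("median split needs at least 2 samples")
    ranked = sorted(values.items(), key=lambda kv: (-kv[1], kv[0]))
    n_high = math.ceil(len(ranked) / 2)
    if n_high < len(ranked) and ranked[n_high - 1][1] == ranked[n_high][1]:
        logger.warning(
            "tie at the median-split boundary (value=%g); broken by sample_id",
            ranked[n_high - 1][1],
        )
    return {
        sid: ("high" if i < n_high else "low") for i, (sid, _) in enumerate(ranked)
    }


def _to_arrays(records: Sequence[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    times = np.array([r.time_months for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    if np.any(times < 0):
        raise ValueError("negative survival times")
    return times, events


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier product-limit estimate over the distinct event times."""
    if not records:
        raise ValueError("no survival records")
    times, events = _to_arrays(records)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    event_times = [float(t) for t in event_rows.index]
    at_risk = [int(r) for r in event_rows["at_risk"]]
    surv = [float(kmf.survival_function_at_times(t).iloc[0]) for t in event_times]
    return KMCurve(event_times=event_times, survival_probs=surv, at_risk=at_risk)


class LogrankResult(NamedTuple):
    chi_square: float
    p_value: float


def logrank_test(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> LogrankResult:
    """Two-group log-rank test; chi-square statistic with 1 df."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    ta, ea = _to_arrays(group_a)
    tb, eb = _to_arrays(group_b)
    if not (ea.any() or eb.any()):
        raise ValueError("log-rank test requires at least one event")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return LogrankResult(float(res.test_statistic), float(res.p_value))


class CoxResult(NamedTuple):
    hazard_ratio: float
    ci_low: float
    ci_high: float
    coef: float
    se: float


def cox_univariate(
    records: Sequence[SurvivalRecord],
    covariate: Mapping[str, float],
    ties: str = "efron",
) -> CoxResult:
    """Univariate Cox proportional-hazards fit; HR with 95% CI.

    The partial likelihood is maximized with Efron handling of tied event
    times (Breslow available via ``ties``). The CI comes from the
    observed-information standard error of the log hazard ratio.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie-handling method: {ties!r}")
    times, events = _to_arrays(records)
    if int(events.sum()) < 2:
        raise ValueError("Cox fit requires at least 2 events")
    x = np.array([covariate[r.sample_id] for r in records], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant; hazard ratio is unidentifiable")
    model = PHReg(times, x[:, None], status=events.astype(int), ties=ties)
    import warnings as _warnings

    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always", ConvergenceWarning)
        try:
            fit = model.fit(disp=False)
        except Exception as exc:  # singular information / optimizer failure
            raise RuntimeError(f"Cox partial-likelihood fit failed: {exc}") from exc
    coef = float(fit.params[0])
    se = float(fit.bse[0])
    if any(issubclass(w.category, ConvergenceWarning) for w in caught):
        raise RuntimeError(
            "Cox partial-likelihood fit did not converge "
            f"(coef={coef:.3g}, se={se:.3g}); the covariate may perfectly "
            "separate the event order"
        )
    if not (math.isfinite(coef) and math.isfinite(se)) or abs(coef) > 500:
        raise RuntimeError("Cox partial-likelihood fit did not converge (degenerate estimate)")
    z = 1.959963984540054  # 97.5% normal quantile
    return CoxResult(
        hazard_ratio=math.exp(coef),
        ci_low=math.exp(coef - z * se),
        ci_high=math.exp(coef + z * se),
        coef=coef,
        se=se,
    )


def km_curve_frame(curve: KMCurve) -> pd.DataFrame:
    """KM curve as a step-function table for TSV export."""
    return pd.DataFrame(
        {
            "time_months": curve.event_times,
            "survival": curve.survival_probs,
            "at_risk": curve.at_risk,
        }
    )
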