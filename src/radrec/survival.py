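"""Kaplan–Meier estimation and log-rank comparison of rule-stratified
overall survival.

The survival clock starts at the first appearance of measurable
enhancement on follow-up MRI.  Patients are stratified by the conjunction
rule (nCBV90 > c1 and proSWMRI ≤ c2 versus the complement); median OS with
a 95% CI and survival rates at 6/12/24 months (month = 30.44 days) are
reported per stratum, compared with the one-degree-of-freedom log-rank
test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import median_survival_times

from .types import ValidationError

DAYS_PER_MONTH = 30.44


@dataclass
class SurvivalCurve:
    event_times: np.ndarray
    survival_prob: np.ndarray
    n_at_risk: np.ndarray
    median_days: Optional[float]
    median_ci95: tuple

    def survival_at(self, days: float) -> float:
        """Step-function survival probability at a given time."""
        idx = np.searchsorted(self.event_times, days, side="right") - 1
        return float(self.survival_prob[idx]) if idx >= 0 else 1.0

    def rates_at_months(self, months: Sequence[float] = (6, 12, 24)) -> dict:
        return {m: 100.0 * self.survival_at(m * DAYS_PER_MONTH) for m in months}


def km_fit(times, events) -> SurvivalCurve:
    """Product-limit (Kaplan–Meier) estimator with Greenwood variance and a
    log–log-transform CI for the median."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    if times.size == 0:
        raise ValidationError("at least one subject required")
    if (times < 0).any():
        raise ValidationError("survival times must be >= 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = (
        kmf.event_table["at_risk"].reindex(kmf.survival_function_.index).to_numpy()
    )
    median = kmf.median_survival_time_
    if np.isinf(median) or np.isnan(median):
        median_days = None
        ci = (None, None)
    else:
        median_days = float(median)
        ci_frame = median_survival_times(kmf.confidence_interval_)
        lo, hi = (float(v) for v in ci_frame.iloc[0].to_numpy())
        ci = (None if np.isinf(lo) else lo, None if np.isinf(hi) else hi)
    return SurvivalCurve(
        event_times=timeline,
        survival_prob=surv,
        n_at_risk=at_risk,
        median_days=median_days,
        median_ci95=ci,
    )


class LogrankResult(NamedTuple):
    chi_square: float
    p_value: float


def logrank_test(times_a, events_a, times_b, events_b) -> LogrankResult:
    """Standard one-degree-of-freedom log-rank test; ties handled by the
    hypergeometric variance."""
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    if times_a.size == 0 or times_b.size == 0:
        raise ValidationError("both groups must be nonempty")
    res = _ll_logrank(
        times_a,
        times_b,
        event_observed_A=np.asarray(events_a).astype(bool),
        event_observed_B=np.asarray(events_b).astype(bool),
    )
    return LogrankResult(chi_square=float(res.test_statistic), p_value=float(res.p_value))
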