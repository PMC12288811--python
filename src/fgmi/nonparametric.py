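"""Nonparametric survival estimators: Kaplan-Meier and Nelson-Aalen.

Both operate on a ``SurvivalSample`` — (time, status, optional weight) triples
where status is a binary event indicator for whichever role the sample plays:
a cause-k event, censoring-as-event (for the censoring distribution G), or the
cause-1 subdistribution outcome (V, I(D=1)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .stepfun import StepFunction

__all__ = ["SurvivalSample", "kaplan_meier", "nelson_aalen"]


@dataclass(frozen=True)
class SurvivalSample:
    """(time, status, weight) triples with positive times and 0/1 status."""

    time: np.ndarray
    status: np.ndarray
    weight: np.ndarray | None = None

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        status = np.asarray(self.status)
        if time.size == 0:
            raise ValueError("empty sample")
        if np.any(time <= 0) or np.any(~np.isfinite(time)):
            raise ValueError("all times must be positive and finite")
        if not np.isin(status, (0, 1)).all():
            raise ValueError("status must be 0/1")
        status = status.astype(float)
        if self.weight is None:
            weight = np.ones_like(time)
        else:
            weight = np.asarray(self.weight, dtype=float)
            if weight.shape != time.shape or np.any(weight <= 0):
                raise ValueError("weights must be positive, one per subject")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "status", status)
        object.__setattr__(self, "weight", weight)

    @property
    def n_events(self) -> float:
        return float(np.sum(self.status * self.weight))


def _risk_table(sample: SurvivalSample):
    """Distinct event times with (weighted) event counts and at-risk sizes."""
    order = np.argsort(sample.time, kind="stable")
    t = sample.time[order]
    d = sample.status[order] * sample.weight[order]
    w = sample.weight[order]
    # n at risk just before t_j = total weight with time >= t_j
    at_risk = np.cumsum(w[::-1])[::-1]
    uniq, first = np.unique(t, return_index=True)
    d_sum = np.add.reduceat(d, first)
    n_risk = at_risk[first]
    keep = d_sum > 0
    return uniq[keep], d_sum[keep], n_risk[keep]


def kaplan_meier(sample: SurvivalSample) -> StepFunction:
    """Product-limit estimate of the survival function.

    S(t) = prod_{t_j <= t} (1 - d_j / n_j), a nonincreasing right-continuous
    step function starting at 1.  A sample with no events yields S = 1
    everywhere (with a warning).
    """
    times, d, n = _risk_table(sample)
    if times.size == 0:
        warnings.warn("no events in sample: survival estimate is constant 1")
        return StepFunction(np.empty(0), np.empty(0), value_before_first=1.0)
    surv = np.cumprod(1.0 - d / n)
    return StepFunction(times, surv, value_before_first=1.0)


def nelson_aalen(sample: SurvivalSample) -> StepFunction:
    """Nelson-Aalen estimate of the cumulative hazard H(t) = sum d_j / n_j."""
    times, d, n = _risk_table(sample)
    if times.size == 0:
        warnings.warn("no events in sample: cumulative hazard estimate is 0")
        return StepFunction(np.empty(0), np.empty(0), value_before_first=0.0)
    return StepFunction(times, np.cumsum(d / n), value_before_first=0.0)
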