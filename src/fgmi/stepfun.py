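"""Right-continuous step functions.

Cumulative hazards, survival curves and baseline cumulative incidences are all
piecewise-constant estimates with jumps at observed event times.  This module
provides the single container used for all of them, with both right-continuous
evaluation ``f(t)`` and left-limit evaluation ``f(t-)`` — the latter is needed
when conditioning on survival past an observed time (e.g. drawing potential
censoring times given ``C > T_i`` uses ``G(T_i-)``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["StepFunction"]


@dataclass(frozen=True)
class StepFunction:
    """A right-continuous step function ``t -> value at largest knot <= t``.

    Parameters
    ----------
    knots : array-like
        Strictly increasing, positive jump locations.
    values : array-like
        Function value at and after each knot (same length as ``knots``).
    value_before_first : float
        Value on ``[0, knots[0])`` — 0 for cumulative hazards, 1 for survival.
    """

    knots: np.ndarray
    values: np.ndarray
    value_before_first: float = 0.0

    def __post_init__(self) -> None:
        knots = np.asarray(self.knots, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if knots.ndim != 1 or values.shape != knots.shape:
            raise ValueError("knots and values must be 1-d arrays of equal length")
        if knots.size and not np.all(np.diff(knots) > 0):
            raise ValueError("knots must be strictly increasing")
        if knots.size and knots[0] <= 0:
            raise ValueError("knots must be positive")
        object.__setattr__(self, "knots", knots)
        object.__setattr__(self, "values", values)

    def __call__(self, t) -> np.ndarray | float:
        """Evaluate right-continuously: value at the largest knot <= t."""
        t_arr = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.knots, t_arr, side="right")
        full = np.concatenate(([self.value_before_first], self.values))
        out = full[idx]
        return out if t_arr.ndim else float(out)

    def left_limit(self, t) -> np.ndarray | float:
        """Evaluate the left limit f(t-): value at the largest knot < t."""
        t_arr = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.knots, t_arr, side="left")
        full = np.concatenate(([self.value_before_first], self.values))
        out = full[idx]
        return out if t_arr.ndim else float(out)

    def jumps(self) -> np.ndarray:
        """Jump sizes at each knot."""
        full = np.concatenate(([self.value_before_first], self.values))
        return np.diff(full)

    def jump_at(self, t, nearest_prior: bool = False) -> np.ndarray | float:
        """Jump size at time(s) ``t`` (0 where t is not a knot).

        With ``nearest_prior=True``, times that do not sit exactly on a knot
        receive the jump of the largest knot <= t instead of 0.
        """
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        jumps = self.jumps()
        idx = np.searchsorted(self.knots, t_arr, side="right") - 1
        valid = idx >= 0
        out = np.zeros_like(t_arr)
        if nearest_prior:
            out[valid] = jumps[idx[valid]]
        else:
            on_knot = valid & np.isclose(
                np.where(valid, self.knots[np.clip(idx, 0, None)], -1.0), t_arr
            )
            out[on_knot] = jumps[idx[on_knot]]
        return out if np.ndim(t) else float(out[0])

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "knots": self.knots.tolist(),
            "values": self.values.tolist(),
            "value_before_first": self.value_before_first,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "StepFunction":
        return cls(
            np.asarray(d["knots"], dtype=float),
            np.asarray(d["values"], dtype=float),
            float(d["value_before_first"]),
        )

    @classmethod
    def from_json(cls, s: str) -> "StepFunction":
        return cls.from_dict(json.loads(s))
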