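"""Right-continuous step functions on [0, inf).

All nonparametric estimators in this package (cumulative transition
hazards, survival curves, state occupation probabilities, the marginal
mean) are piecewise-constant cadlag paths; :class:`StepFunction` is the
one container they share.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class StepFunction:
    """A right-continuous piecewise-constant function.

    Parameters
    ----------
    times : array
        Strictly increasing jump times.
    values : array
        Function value on ``[times[k], times[k+1])``.
    initial : float
        Value on ``[0, times[0])`` (and at negative arguments' limit).
    """

    times: np.ndarray
    values: np.ndarray
    initial: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-d arrays of equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("jump times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __call__(self, t) -> np.ndarray | float:
        """Evaluate f(t) (right-continuous convention)."""
        t_arr = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t_arr, side="right")
        padded = np.concatenate(([self.initial], self.values))
        out = padded[idx]
        return out if t_arr.ndim else float(out)

    def left_limit(self, t) -> np.ndarray | float:
        """Evaluate f(t-)."""
        t_arr = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t_arr, side="left")
        padded = np.concatenate(([self.initial], self.values))
        out = padded[idx]
        return out if t_arr.ndim else float(out)

    def integrate(self, t: float) -> float:
        """Exact integral of the step function over [0, t]."""
        if t < 0:
            raise ValueError("upper limit must be nonnegative")
        if self.times.size == 0 or t <= self.times[0]:
            return self.initial * t
        knots = np.concatenate(([0.0], self.times, [t]))
        knots = np.clip(knots, 0.0, t)
        vals = np.concatenate(([self.initial], self.values))
        return float(np.sum(vals * np.diff(knots)))

    @property
    def increments(self) -> np.ndarray:
        """Jump sizes at each jump time."""
        prev = np.concatenate(([self.initial], self.values[:-1]))
        return self.values - prev

    @staticmethod
    def from_increments(times, increments, initial: float = 0.0) -> "StepFunction":
        """Build the cumulative step function from jump sizes."""
        times = np.asarray(times, dtype=float)
        increments = np.asarray(increments, dtype=float)
        return StepFunction(times, initial + np.cumsum(increments), initial)
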