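"""Nonparametric estimators for multistate event histories.

All estimators are exact step functions on the observed event-time grid
(no interpolation or smoothing):

* Nelson-Aalen cumulative transition hazards -- in a non-Markov model
  with random censoring these estimate cumulative *partly conditional
  transition rates* (conditioning on the current state only);
* Kaplan-Meier product-limit survival for first-event analyses;
* the Aalen-Johansen matrix-product estimator of transition
  probabilities, whose start-at-origin row gives state occupation
  probabilities (consistent under random censoring even without the
  Markov property);
* the marginal mean number of recurrent events mu(t), the average
  length of stay in hospital, and the between-arm RR(t) ratio of
  hospitalizations per time alive;
* basic (reflected-percentile) bootstrap confidence limits from
  subject-level resampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .history import CENSORED, DEAD, HOME, HOSPITAL, EventHistory, HistoryError
from .stepfun import StepFunction

_TRANSIENT = (HOME, HOSPITAL)
_STATES = (HOME, HOSPITAL, DEAD)
_ALLOWED = ((HOME, HOSPITAL), (HOME, DEAD), (HOSPITAL, HOME), (HOSPITAL, DEAD))


def _risk_window_counts(start, stop, grid):
    """Number of intervals with start < t <= stop, per t in sorted ``grid``."""
    nb = grid.size + 1
    ia = np.searchsorted(grid, start, side="right")
    ib = np.searchsorted(grid, stop, side="right")
    return np.cumsum(np.bincount(ia, minlength=nb)
                     - np.bincount(ib, minlength=nb))[:grid.size]


def nelson_aalen(history: EventHistory, transition=(HOME, HOSPITAL),
                 ) -> StepFunction:
    """Cumulative hazard / partly conditional rate of one transition.

    Increment at an event time = (number of observed h->j transitions) /
    (subjects in state h just prior), per the left-limit risk-set
    convention; censored intervals contribute risk time only.
    """
    h, j = transition
    if (h, j) not in _ALLOWED:
        raise HistoryError(f"transition {transition} not in allowed set")
    df = history.table
    in_h = df["from"].to_numpy() == h
    start = df["start"].to_numpy(float)[in_h]
    stop = df["stop"].to_numpy(float)[in_h]
    ev = (df["to"].to_numpy()[in_h] == j) & (df["status"].to_numpy()[in_h] == 1)
    et = np.unique(stop[ev])
    if et.size == 0:
        return StepFunction(np.array([]), np.array([]), 0.0)
    d = np.bincount(np.searchsorted(et, stop[ev]), minlength=et.size).astype(float)
    Y = _risk_window_counts(start, stop, et)
    assert np.all(Y > 0), "empty risk set at an observed transition time"
    return StepFunction.from_increments(et, d / Y)


def kaplan_meier(times, status) -> StepFunction:
    """Product-limit estimate of S(t) from first-event times.

    ``status`` is 1 for an observed event, 0 for censoring; ties between
    events and censorings at the same time keep the censored subjects in
    the risk set (censoring acts after events).
    """
    times = np.asarray(times, dtype=float)
    status = np.asarray(status).astype(bool)
    if np.any(times < 0):
        raise ValueError("event times must be nonnegative")
    order = np.argsort(times, kind="stable")
    t, s = times[order], status[order]
    uniq = np.unique(t[s])
    if uniq.size == 0:
        return StepFunction(np.array([]), np.array([]), 1.0)
    at_risk = t.size - np.searchsorted(t, uniq, side="left")
    d = np.bincount(np.searchsorted(uniq, t[s]), minlength=uniq.size).astype(float)
    return StepFunction(uniq, np.cumprod(1.0 - d / at_risk), 1.0)


@dataclass(frozen=True)
class TransitionProbabilityPath:
    """Aalen-Johansen transition probability matrices P(s, t).

    ``matrices[k]`` is P(s, times[k]); P(s, t) is a right-continuous
    step function of t equal to the identity for t <= times[0]-.
    """

    s: float
    times: np.ndarray
    matrices: np.ndarray            # (K, m, m)
    states: tuple = _STATES

    def __post_init__(self):
        if self.matrices.size:
            rows = self.matrices.sum(axis=2)
            if not np.allclose(rows, 1.0, atol=1e-10):
                raise AssertionError("transition matrix rows must sum to 1")
            if self.matrices.min() < -1e-12 or self.matrices.max() > 1 + 1e-12:
                raise AssertionError("transition probabilities outside [0, 1]")

    def __call__(self, t: float) -> np.ndarray:
        m = len(self.states)
        idx = np.searchsorted(self.times, t, side="right") - 1
        return np.eye(m) if idx < 0 else self.matrices[idx]

    def occupation(self, from_state=HOME) -> dict[int, StepFunction]:
        i = self.states.index(from_state)
        init = np.eye(len(self.states))[i]
        return {st: StepFunction(self.times, self.matrices[:, i, j], init[j])
                for j, st in enumerate(self.states)}


def aalen_johansen(history: EventHistory, s: float = 0.0,
                   ) -> TransitionProbabilityPath:
    """Matrix product of (I + dLambda(u)) over event times u in (s, t]."""
    df = history.table
    frm = df["from"].to_numpy()
    to = df["to"].to_numpy()
    start = df["start"].to_numpy(float)
    stop = df["stop"].to_numpy(float)
    obs = df["status"].to_numpy() == 1

    et = np.unique(stop[obs & (stop > s)])
    m = len(_STATES)
    if et.size == 0:
        return TransitionProbabilityPath(s, np.array([]),
                                         np.empty((0, m, m)), _STATES)
    dA = np.zeros((et.size, m, m))
    for h in _TRANSIENT:
        in_h = frm == h
        Y = _risk_window_counts(start[in_h], stop[in_h], et).astype(float)
        for (hh, j) in _ALLOWED:
            if hh != h:
                continue
            sel = in_h & obs & (to == j) & (stop > s)
            if not sel.any():
                continue
            d = np.bincount(np.searchsorted(et, stop[sel]),
                            minlength=et.size).astype(float)
            with np.errstate(invalid="ignore", divide="ignore"):
                inc = np.where(d > 0, d / Y, 0.0)
            dA[:, h, j] = inc
        dA[:, h, h] = -dA[:, h].sum(axis=1)
    P = np.empty((et.size, m, m))
    acc = np.eye(m)
    for k in range(et.size):
        acc = acc @ (np.eye(m) + dA[k])
        P[k] = acc
    return TransitionProbabilityPath(s, et, P, _STATES)


def state_occupation(history: EventHistory) -> dict[int, StepFunction]:
    """Occupation probabilities Q_l(t) = P(X_t = l | X_0 = 0), l in {0,1,2}."""
    return aalen_johansen(history, s=0.0).occupation(HOME)


def average_length_of_stay(q1: StepFunction, t: float) -> float:
    """Expected days in hospital by ``t``: the integral of Q_1 over [0, t]."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    return q1.integrate(t)


def marginal_mean(q0: StepFunction, lam01: StepFunction, t: float) -> float:
    """Marginal mean number of hospitalizations by ``t``.

    mu(t) = sum over event times u_k <= t of Q_0(u_k-) dLambda_01(u_k),
    with the left-limit occupation making the estimator predictable and
    reproducing the mean observed event count exactly without censoring.
    """
    keep = lam01.times <= t
    uk = lam01.times[keep]
    return float(np.sum(q0.left_limit(uk) * lam01.increments[keep]))


def marginal_mean_path(q0: StepFunction, lam01: StepFunction) -> StepFunction:
    inc = q0.left_limit(lam01.times) * lam01.increments
    return StepFunction.from_increments(lam01.times, inc)


@dataclass(frozen=True)
class RatioSummary:
    """RR(t): expected hospitalizations per expected days alive, by arm."""

    t: float
    events_trt: float
    surv_trt: float                 # integral of 1 - Q2 over [0, t], treated
    events_uc: float
    surv_uc: float

    @property
    def ratio(self) -> float:
        return (self.events_trt / self.surv_trt) / (self.events_uc / self.surv_uc)


def rr_ratio(mu_trt: StepFunction, q2_trt: StepFunction,
             mu_uc: StepFunction, q2_uc: StepFunction, t: float) -> RatioSummary:
    """Between-arm ratio of hospitalizations per time alive up to ``t``."""
    surv_trt = t - q2_trt.integrate(t)
    surv_uc = t - q2_uc.integrate(t)
    if surv_trt <= 0 or surv_uc <= 0:
        raise ValueError("zero integrated survival in one arm")
    return RatioSummary(t, mu_trt(t), surv_trt, mu_uc(t), surv_uc)


def resample_subjects(history: EventHistory, rng) -> EventHistory:
    """Subject-level (cluster) bootstrap resample with fresh ids."""
    df = history.table
    ids = history.subject_ids
    pick = rng.integers(0, len(ids), size=len(ids))
    blocks = {i: g.index.to_numpy() for i, g in df.groupby("id", sort=False)}
    rows = [blocks[ids[p]] for p in pick]
    out = df.loc[np.concatenate(rows)].copy()
    out["id"] = np.repeat(np.arange(len(pick)), [r.size for r in rows])
    return EventHistory(out, structure=history.structure, validate=False)


def basic_bootstrap_ci(statistic, history: EventHistory, B: int = 1000,
                       level: float = 0.95, rng=None):
    """Basic bootstrap limits 2*theta_hat - q_(1-a/2), 2*theta_hat - q_(a/2).

    ``statistic`` maps an :class:`EventHistory` to a float or an array
    (e.g. a curve evaluated on a fixed grid); subjects are resampled as
    clusters to respect within-subject dependence.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    rng = np.random.default_rng(rng)
    theta = np.asarray(statistic(history), dtype=float)
    draws = np.stack([np.asarray(statistic(resample_subjects(history, rng)),
                                 dtype=float) for _ in range(B)])
    alpha = 1.0 - level
    q_lo, q_hi = np.quantile(draws, [alpha / 2, 1 - alpha / 2], axis=0)
    return 2 * theta - q_hi, 2 * theta - q_lo


def step_to_frame(sf: StepFunction, lower: StepFunction | None = None,
                  upper: StepFunction | None = None) -> pd.DataFrame:
    """Tidy export: one row per jump time (time, estimate[, lower, upper])."""
    out = pd.DataFrame({"time": sf.times, "estimate": sf.values})
    if lower is not None:
        out["lower"] = lower(sf.times)
    if upper is not None:
        out["upper"] = upper(sf.times)
    return out
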