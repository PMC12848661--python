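"""Semiparametric models for counting-process data.

``cox_fit`` maximises the stratified Breslow partial likelihood by
Newton's method on start-stop (Andersen-Gill) data and returns
model-based and robust cluster-sandwich covariances plus Breslow
baseline-hazard increments.  One engine covers

* the cause-specific Cox model (single event per subject),
* the Andersen-Gill recurrent-event model (no strata), and
* the Prentice-Williams-Peterson model on the total-time scale
  (strata = number of previous events).

``ghosh_lin_fit`` solves the IPCW-weighted proportional-rates
estimating equation of the Ghosh-Lin marginal rate model for recurrent
events stopped at death, with the censoring distribution estimated by a
Kaplan-Meier curve (pooled over arms by default).

Ties are handled with the Breslow approximation throughout: simulated
event times are continuous, so ties only arise in user-supplied data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .history import DEAD, HOME, HOSPITAL, EventHistory
from .stepfun import StepFunction

_MAX_ITER = 25
_RTOL = 1e-9
_BETA_BOUND = 30.0  # |beta| beyond this flags a monotone likelihood


@dataclass(frozen=True)
class ModelSpec:
    """What to fit on a long-format dataset.

    ``strata=None`` gives Cox/AG; a column name (e.g. ``"prev_events"``)
    gives the PWP stratification.
    """

    covariates: tuple[str, ...]
    strata: str | None = None
    variance: str = "robust"       # default variance for Wald tests
    ties: str = "breslow"

    def __post_init__(self):
        if self.ties != "breslow":
            raise ValueError("only the Breslow ties approximation is implemented")
        if self.variance not in ("robust", "model"):
            raise ValueError("variance must be 'robust' or 'model'")


@dataclass
class SemiparamFit:
    coef: np.ndarray
    cov_model: np.ndarray
    cov_robust: np.ndarray
    covariates: tuple[str, ...]
    baseline: dict
    n_events: int
    loglik: float
    converged: bool
    n_iter: int
    monotone: bool
    default_variance: str = "robust"

    def se(self, variance: str | None = None) -> np.ndarray:
        cov = self.cov_robust if (variance or self.default_variance) == "robust" \
            else self.cov_model
        return np.sqrt(np.diag(cov))

    def summary(self) -> pd.DataFrame:
        rows = [wald_test(self, name).as_row() for name in self.covariates]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class WaldResult:
    covariate: str
    estimate: float
    se: float
    z: float
    p: float
    hr: float
    ci_low: float
    ci_high: float

    def as_row(self) -> dict:
        return {"covariate": self.covariate, "estimate": self.estimate,
                "se": self.se, "z": self.z, "p": self.p, "HR": self.hr,
                "ci_low": self.ci_low, "ci_high": self.ci_high}


class MonotoneLikelihoodError(RuntimeError):
    pass


# ----------------------------------------------------------------------
# Breslow partial-likelihood engine


class _StratumData:
    """Precomputed risk-window indices for one stratum."""

    __slots__ = ("et", "d", "ia", "ib", "X", "ev", "ev_idx", "rows")

    def __init__(self, start, stop, event, X, rows):
        ev = event.astype(bool)
        self.et = np.unique(stop[ev])                  # ordered event times
        self.d = np.bincount(np.searchsorted(self.et, stop[ev]),
                             minlength=self.et.size).astype(float)
        # row j is at risk at event times et[ia[j]:ib[j]]  (start < t <= stop)
        self.ia = np.searchsorted(self.et, start, side="right")
        self.ib = np.searchsorted(self.et, stop, side="right")
        self.X = X
        self.ev = ev
        self.ev_idx = np.searchsorted(self.et, stop[ev])
        self.rows = rows                               # indices into full data

    def sums(self, beta):
        """S0, S1, S2 at each event time; eta and exp(eta) per row."""
        E, p = self.et.size, self.X.shape[1]
        eta = self.X @ beta
        w = np.exp(eta)
        nb = E + 1

        def windowed(vals):
            return np.cumsum(np.bincount(self.ia, vals, minlength=nb)
                             - np.bincount(self.ib, vals, minlength=nb))[:E]

        S0 = windowed(w)
        S1 = np.empty((E, p))
        S2 = np.empty((E, p, p))
        for a in range(p):
            S1[:, a] = windowed(w * self.X[:, a])
            for b in range(a, p):
                S2[:, a, b] = S2[:, b, a] = windowed(
                    w * self.X[:, a] * self.X[:, b])
        return eta, w, S0, S1, S2


def _prepare(df: pd.DataFrame, covariates, strata, start_col, stop_col,
             event_col):
    X = df[list(covariates)].to_numpy(float)
    center = X.mean(axis=0) if len(df) else np.zeros(X.shape[1])
    Xc = X - center
    start = df[start_col].to_numpy(float)
    stop = df[stop_col].to_numpy(float)
    event = df[event_col].to_numpy(int)
    if strata is None:
        groups = {None: np.arange(len(df))}
    else:
        codes, uniq = pd.factorize(df[strata], sort=True)
        groups = {uniq[g]: np.flatnonzero(codes == g) for g in range(len(uniq))}
    data = [_StratumData(start[r], stop[r], event[r], Xc[r], r)
            for _, r in groups.items()]
    return data, list(groups), center


def _loglik_grad_hess(data, beta):
    p = beta.size
    ll, grad, hess = 0.0, np.zeros(p), np.zeros((p, p))
    for sd in data:
        if sd.et.size == 0:
            continue
        eta, w, S0, S1, S2 = sd.sums(beta)
        ll += eta[sd.ev].sum() - float(sd.d @ np.log(S0))
        xbar = S1 / S0[:, None]
        grad += sd.X[sd.ev].sum(axis=0) - sd.d @ xbar
        hess -= np.einsum("k,kab->ab", sd.d, S2 / S0[:, None, None]) \
            - np.einsum("k,ka,kb->ab", sd.d, xbar, xbar)
    return ll, grad, hess


def cox_fit(df: pd.DataFrame, spec: ModelSpec, *, cluster: str = "id",
            start_col: str = "start", stop_col: str = "stop",
            event_col: str = "event") -> SemiparamFit:
    """Stratified Breslow partial-likelihood fit on start-stop data.

    Raises :class:`MonotoneLikelihoodError` when the likelihood has no
    interior maximum (a coefficient diverges).
    """
    n_events = int(df[event_col].sum())
    if n_events == 0:
        raise ValueError("no outcome events in the data")
    data, stratum_keys, center = _prepare(
        df, spec.covariates, spec.strata, start_col, stop_col, event_col)
    p = len(spec.covariates)
    beta = np.zeros(p)
    ll, grad, hess = _loglik_grad_hess(data, beta)
    converged = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise MonotoneLikelihoodError(
                "singular information matrix (collinear design or "
                "monotone likelihood)") from exc
        # step-halving on overshoot
        for _ in range(30):
            cand = beta + step
            ll_new, grad_new, hess_new = _loglik_grad_hess(data, cand)
            if (np.isfinite(ll_new) and np.all(np.isfinite(hess_new))
                    and ll_new >= ll - 1e-12):
                break
            step *= 0.5
        else:  # pragma: no cover
            break
        done = abs(ll_new - ll) < _RTOL * (abs(ll) + 1.0)
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if done:
            converged = True
            break
    if np.max(np.abs(beta)) > _BETA_BOUND \
            or not (np.all(np.isfinite(beta)) and np.all(np.isfinite(hess))):
        raise MonotoneLikelihoodError(
            "coefficient diverged; the partial likelihood appears monotone")

    info = -hess
    try:
        cov_model = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise MonotoneLikelihoodError("singular information at the optimum") from exc
    # separation/monotone likelihood inflates the model SE without bound;
    # flag when the SE spans an absurd range on the covariate's own scale
    spans = np.array([np.ptp(df[c].to_numpy(float)) for c in spec.covariates])
    if np.any(np.sqrt(np.diag(cov_model)) * spans > 50.0):
        raise MonotoneLikelihoodError(
            "standard error diverged (likely monotone likelihood / "
            "complete separation)")

    # robust cluster sandwich from per-row score residuals
    resid = np.zeros((len(df), p))
    baseline = {}
    for key, sd in zip(stratum_keys, data):
        if sd.et.size == 0:
            baseline[key] = StepFunction(np.array([]), np.array([]))
            continue
        eta, w, S0, S1, S2 = sd.sums(beta)
        xbar = S1 / S0[:, None]
        dL = sd.d / S0                                  # Breslow increments
        A = np.concatenate(([0.0], np.cumsum(dL)))
        B = np.vstack((np.zeros(p), np.cumsum(xbar * dL[:, None], axis=0)))
        r = -w[:, None] * (sd.X * (A[sd.ib] - A[sd.ia])[:, None]
                           - (B[sd.ib] - B[sd.ia]))
        r[sd.ev] += sd.X[sd.ev] - xbar[sd.ev_idx]
        resid[sd.rows] = r
        # rescale baseline to covariate value zero (X was centered)
        baseline[key] = StepFunction.from_increments(
            sd.et, dL * float(np.exp(-center @ beta)))

    codes, _ = pd.factorize(df[cluster])
    U = np.zeros((codes.max() + 1, p))
    np.add.at(U, codes, resid)
    cov_robust = cov_model @ (U.T @ U) @ cov_model

    return SemiparamFit(beta, cov_model, cov_robust, tuple(spec.covariates),
                        baseline, n_events, float(ll), converged, it, False,
                        default_variance=spec.variance)


def wald_test(fit: SemiparamFit, covariate: str,
              variance: str | None = None) -> WaldResult:
    """Two-sided Wald test of 'no influence' for one coefficient."""
    j = fit.covariates.index(covariate)
    se = float(fit.se(variance)[j])
    if not se > 0:
        raise ValueError("zero or undefined standard error")
    b = float(fit.coef[j])
    z = b / se
    p = 2.0 * stats.norm.sf(abs(z))
    lo, hi = np.exp(b - 1.959964 * se), np.exp(b + 1.959964 * se)
    return WaldResult(covariate, b, se, z, p, float(np.exp(b)), lo, hi)


# ----------------------------------------------------------------------
# Ghosh-Lin marginal rate model


def _censoring_km(followup, censored, times_query):
    """P(C > t-) from the reversed Kaplan-Meier of the censoring times."""
    order = np.argsort(followup, kind="stable")
    t, c = followup[order], censored[order]
    uniq = np.unique(t[c])
    at_risk = t.size - np.searchsorted(t, uniq, side="left")
    d = np.bincount(np.searchsorted(uniq, t[c]), minlength=uniq.size).astype(float)
    surv = np.cumprod(1.0 - d / at_risk)
    G = StepFunction(uniq, surv, 1.0)
    return G.left_limit(times_query)


def ghosh_lin_fit(history: EventHistory, covariates=("Z",),
                  variance: str = "robust",
                  tau: float | None = None) -> SemiparamFit:
    """IPCW proportional-rates fit for recurrent events stopped at death.

    Every subject remains in the (weighted) risk set after death with a
    frozen weight, reflecting that the marginal rate averages over the
    dead (for whom ``dN = 0``); censoring removes subjects and is
    compensated by inverse-probability-of-censoring weights from a
    pooled Kaplan-Meier of the censoring distribution.  The sandwich
    variance treats the weights as known.

    ``tau`` restricts the estimating equation to events in ``[0, tau]``.
    Near the end of follow-up the censoring survival is close to zero
    and a handful of events carry enormous weights, so estimates using
    the full range can be noise-dominated; choosing ``tau`` where the
    estimated censoring survival is still moderate (say above 10-20%)
    is the usual remedy (weight trimming is deliberately not offered).
    """
    df = history.table
    per = df.groupby("id", sort=True)
    followup = per["stop"].max().to_numpy(float)
    last_to = per["to"].last().to_numpy(int)
    died = last_to == DEAD
    X = per[list(covariates)].first().to_numpy(float)
    ids = per["stop"].max().index.to_numpy()
    n, p = X.shape

    ev = df[(df["from"] == HOME) & (df["to"] == HOSPITAL)]
    if tau is not None:
        ev = ev[ev["stop"] <= tau]
    ev_subject = np.searchsorted(ids, ev["id"].to_numpy())
    ev_time = ev["stop"].to_numpy(float)
    if ev_time.size == 0:
        raise ValueError("no recurrent events in the data (below tau)")

    et = np.unique(ev_time)                         # E ordered event times
    # weight matrix W[k, j] = I(observable at t_k) / G((t_k ^ X_j)-)
    m = np.minimum(et[:, None], followup[None, :])
    avail = died[None, :] | (et[:, None] <= followup[None, :])
    G = _censoring_km(followup, ~died, m.ravel()).reshape(m.shape)
    if np.any(avail & (G <= 0)):
        raise ValueError(
            "censoring Kaplan-Meier reaches zero before the last recurrent "
            "event: IPCW weights blow up. Restrict the time horizon or "
            "consider administrative censoring.")
    W = np.where(avail, 1.0 / np.where(G > 0, G, 1.0), 0.0)

    k_of_event = np.searchsorted(et, ev_time)
    w_event = W[k_of_event, ev_subject]             # 1/G(t-) at own event

    center = X.mean(axis=0)
    Xc = X - center

    def quantities(beta):
        ex = np.exp(Xc @ beta)
        S0 = W @ ex
        S1 = W @ (ex[:, None] * Xc)
        xbar = S1 / S0[:, None]
        score = ((Xc[ev_subject] - xbar[k_of_event]) * w_event[:, None]).sum(0)
        S2 = np.einsum("kj,j,ja,jb->kab", W, ex, Xc, Xc)
        V = S2 / S0[:, None, None] - np.einsum("ka,kb->kab", xbar, xbar)
        dN = np.bincount(k_of_event, w_event, minlength=et.size)
        A = np.einsum("k,kab->ab", dN, V)
        return ex, S0, xbar, score, A, dN

    beta = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        ex, S0, xbar, score, A, dN = quantities(beta)
        try:
            step = np.linalg.solve(A, score)
        except np.linalg.LinAlgError as exc:
            raise MonotoneLikelihoodError("singular design in rate model") from exc
        beta = beta + step
        if np.max(np.abs(step)) < 1e-9:
            converged = True
            break
    if np.max(np.abs(beta)) > _BETA_BOUND:
        raise MonotoneLikelihoodError("rate-model coefficient diverged")

    ex, S0, xbar, score, A, dN = quantities(beta)
    dmu0 = dN / S0                                   # baseline mean increments
    A_inv = np.linalg.inv(A)

    # per-subject estimating-function residuals
    psi = np.zeros((n, p))
    np.add.at(psi, ev_subject,
              (Xc[ev_subject] - xbar[k_of_event]) * w_event[:, None])
    s = dmu0 @ W                                     # integral of w_j dmu0
    c = np.einsum("k,kj,ka->ja", dmu0, W, xbar)      # integral of w_j xbar dmu0
    psi -= ex[:, None] * (Xc * s[:, None] - c)

    cov_robust = A_inv @ (psi.T @ psi) @ A_inv
    baseline = {None: StepFunction.from_increments(
        et, dmu0 * float(np.exp(-center @ beta)))}
    return SemiparamFit(beta, A_inv, cov_robust, tuple(covariates), baseline,
                        int(ev_time.size), np.nan, converged, it, False,
                        default_variance=variance)
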