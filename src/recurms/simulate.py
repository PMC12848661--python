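"""Synthetic event-history generator for the nine simulation scenarios.

The generator emulates a two-arm heart-failure trial with recurrent
hospitalizations, discharges, death and heavy right-censoring: 600
subjects (300 per arm), all starting alive at home at day 0.  Event
times come from nested competing-risks experiments: from the current
state a sojourn is drawn with the combined hazard of all active causes
(inversion method) and a categorical experiment picks the cause with
probability proportional to its rate; the clock then restarts in the
next state (waiting-time scale; equivalent to calendar time for the
constant baseline rates used here).

Scenario grid (daily baseline rates 0.002 / 0.0007 / 0.004 / 0.00075 for
home->hospital, home->death, discharge, death-in-hospital):

====  ============  ==========  ======================  ==============
id    structure     frailty     censoring               extra
====  ============  ==========  ======================  ==============
1     illness-death no          random exp(0.00045)     --
2     illness-death Gamma(2,1)  random exp(0.00045)     --
3     illness-death no          state-dependent         --
4     illness-death Gamma(2,1)  state-dependent         --
5-8   progressive   as 1-4      as 1-4                  rates x (1+0.1k)
9     progressive   no          state-dependent         entry-time rates,
                                                        lam12 base 0.0011
====  ============  ==========  ======================  ==============

k is the number of previous states (= completed transitions).  A
multiplicative gamma frailty (shape 2, normalized to mean one) on all
event hazards induces a marginally non-Markov process whose pooled
partly conditional rate bends below the Markov straight line;
state-dependent censoring is a third competing risk with hazard
0.00045*(1+0.05k) (independent but not random censoring).  Scenario 9
multiplies each event hazard by (entry time into the current state /
1000); that factor degenerates to 0 for the initial state entered at
time 0 -- which would freeze every subject at study start -- so it is
anchored at 1 there and applied literally for every later state.
Treatment alternatives multiply the treated arm's home->hospital rate
by exp(-0.1625) (hazard ratio 0.85).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .history import CENSORED, DEAD, HOME, HOSPITAL, EventHistory, TransitionRecord

BASE_RATES = (0.002, 0.0007, 0.004, 0.00075)
CENS_RATE = 0.00045
ALT_LOG_HR = -0.1625


@dataclass(frozen=True)
class HazardSpec:
    """Per-transition baseline rates and their history modifiers."""

    lam01: float = BASE_RATES[0]
    lam02: float = BASE_RATES[1]
    lam10: float = BASE_RATES[2]
    lam12: float = BASE_RATES[3]
    #: progressive scenarios multiply every rate by (1 + factor * k)
    progressive_factor: float = 0.0
    #: scenario 9 multiplies event rates by (1 + entry time/1000)
    entry_time_factor: bool = False
    #: log hazard ratio applied to the treated arm's 0->1 rate
    treatment_log_hr: float = 0.0

    def __post_init__(self):
        if min(self.lam01, self.lam02, self.lam10, self.lam12) < 0:
            raise ValueError("rates must be nonnegative")


@dataclass(frozen=True)
class FrailtySpec:
    """Multiplicative gamma frailty on all event hazards.

    Shape 2 with scale 1/2 gives the mean-one normalization standard in
    frailty modelling: the subject-specific multiplier averages to 1, so
    the population time scale matches the no-frailty scenarios while the
    induced history dependence destroys the Markov property.
    """

    enabled: bool = False
    shape: float = 2.0
    scale: float = 0.5


@dataclass(frozen=True)
class CensoringSpec:
    #: "random" = one exponential censoring time per subject, applied if it
    #: precedes death; "state-dependent" = third competing risk per sojourn
    mode: str = "random"
    rate: float = CENS_RATE
    state_factor: float = 0.05

    def __post_init__(self):
        if self.mode not in ("random", "state-dependent"):
            raise ValueError(f"unknown censoring mode {self.mode!r}")
        if self.rate <= 0:
            raise ValueError("censoring rate must be positive")


@dataclass(frozen=True)
class ScenarioConfig:
    scenario: str = "1"
    structure: str = "illness-death"
    hazards: HazardSpec = field(default_factory=HazardSpec)
    frailty: FrailtySpec = field(default_factory=FrailtySpec)
    censoring: CensoringSpec = field(default_factory=CensoringSpec)
    n_subjects: int = 600
    n_treated: int = 300
    n_reps: int = 1000
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ScenarioConfig":
        d = json.loads(text)
        return cls(hazards=HazardSpec(**d.pop("hazards")),
                   frailty=FrailtySpec(**d.pop("frailty")),
                   censoring=CensoringSpec(**d.pop("censoring")), **d)


def scenario_catalog(n_subjects: int = 600, n_treated: int = 300,
                     n_reps: int = 1000, seed: int = 0,
                     ) -> dict[str, ScenarioConfig]:
    """The nine null scenarios plus the HR-0.85 alternatives ("alt-<k>")."""
    cat: dict[str, ScenarioConfig] = {}
    for i in range(1, 10):
        progressive = i >= 5
        frailty = FrailtySpec(enabled=i in (2, 4, 6, 8))
        cens = CensoringSpec(mode="state-dependent" if i in (3, 4, 7, 8, 9)
                             else "random")
        haz = HazardSpec(progressive_factor=0.1 if progressive else 0.0,
                         entry_time_factor=(i == 9),
                         lam12=0.0011 if i == 9 else BASE_RATES[3])
        cat[str(i)] = ScenarioConfig(
            scenario=str(i),
            structure="progressive" if progressive else "illness-death",
            hazards=haz, frailty=frailty, censoring=cens,
            n_subjects=n_subjects, n_treated=n_treated, n_reps=n_reps, seed=seed)
    for i in range(1, 10):
        base = cat[str(i)]
        cat[f"alt-{i}"] = replace(
            base, scenario=f"alt-{i}",
            hazards=replace(base.hazards, treatment_log_hr=ALT_LOG_HR))
    return cat


def get_scenario(scenario_id: str | int, **kwargs) -> ScenarioConfig:
    cat = scenario_catalog(**kwargs)
    key = str(scenario_id)
    if key not in cat:
        raise KeyError(f"unknown scenario {scenario_id!r}")
    return cat[key]


def draw_sojourn(rates, rng) -> tuple[float, int]:
    """One nested competing-risks experiment with constant cause rates.

    Returns the exponential waiting time drawn with the combined rate and
    the cause index, picked with probability rate_c / total.
    """
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be nonnegative")
    total = rates.sum()
    if total <= 0:
        raise ValueError("all cause rates are zero: sojourn is infinite")
    wait = rng.exponential(1.0 / total)
    cause = int(np.searchsorted(np.cumsum(rates) / total, rng.random(),
                                side="right"))
    return wait, min(cause, rates.size - 1)


def _active_rates(cfg: ScenarioConfig, state, k, entry, frailty, z):
    """Cause rates (move, die, censor) for subjects in transient states."""
    h = cfg.hazards
    mult = frailty.copy()
    if h.progressive_factor:
        mult = mult * (1.0 + h.progressive_factor * k)
    if h.entry_time_factor:
        # literal factor (entry/1000) wherever defined; the initial state is
        # entered at time 0 where the printed factor degenerates to 0, so it
        # is anchored at 1 there (see the module docstring)
        mult = mult * np.where(entry > 0, entry / 1000.0, 1.0)
    at_home = state == HOME
    r_move = np.where(at_home, h.lam01 * np.exp(h.treatment_log_hr * z),
                      h.lam10) * mult
    r_die = np.where(at_home, h.lam02, h.lam12) * mult
    if cfg.censoring.mode == "state-dependent":
        r_cens = cfg.censoring.rate * (1.0 + cfg.censoring.state_factor * k)
        r_cens = np.broadcast_to(r_cens, r_move.shape).astype(float)
    else:
        r_cens = np.zeros_like(r_move)
    return r_move, r_die, r_cens


_MAX_TRANSITIONS = 10_000  # absorption is a.s.; guard against bad configs


def _simulate_cohort(cfg: ScenarioConfig, z: np.ndarray, frailty: np.ndarray,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Vectorised nested competing-risks simulation for ``len(z)`` subjects."""
    n = z.size
    cens_time = (rng.exponential(1.0 / cfg.censoring.rate, size=n)
                 if cfg.censoring.mode == "random" else None)

    idx = np.arange(n)
    state = np.full(n, HOME)
    k = np.zeros(n, dtype=int)        # number of previous states (transitions)
    now = np.zeros(n)
    entry = np.zeros(n)
    active = np.ones(n, dtype=bool)

    rows_id, rows_from, rows_to, rows_start, rows_stop, rows_status = \
        [], [], [], [], [], []
    for _ in range(_MAX_TRANSITIONS):
        if not active.any():
            break
        a = idx[active]
        r_move, r_die, r_cens = _active_rates(
            cfg, state[a], k[a], entry[a], frailty[a], z[a])
        total = r_move + r_die + r_cens
        if np.any(total <= 0):
            raise ValueError("zero total rate: subject would never be absorbed")
        wait = rng.exponential(1.0, size=a.size) / total
        u = rng.random(a.size) * total
        stop = now[a] + wait
        move = u < r_move
        die = (~move) & (u < r_move + r_die)
        to = np.where(move, np.where(state[a] == HOME, HOSPITAL, HOME),
                      np.where(die, DEAD, CENSORED))

        rows_id.append(a)
        rows_from.append(state[a].copy())
        rows_to.append(to)
        rows_start.append(now[a].copy())
        rows_stop.append(stop)
        rows_status.append((to != CENSORED).astype(int))

        now[a] = stop
        entry[a] = stop
        state[a] = np.where(move, to, state[a])
        k[a] += 1
        absorbed = a[~move]
        active[absorbed] = False
    else:  # pragma: no cover - guarded by rate checks
        raise RuntimeError("subject not absorbed after maximum transitions")

    df = pd.DataFrame({
        "id": np.concatenate(rows_id),
        "from": np.concatenate(rows_from),
        "to": np.concatenate(rows_to),
        "start": np.concatenate(rows_start),
        "stop": np.concatenate(rows_stop),
        "status": np.concatenate(rows_status),
    })
    if cens_time is not None:
        c = cens_time[df["id"].to_numpy()]
        keep = df["start"].to_numpy() < c
        df = df[keep]
        c = c[keep]
        cut = df["stop"].to_numpy() > c
        df.loc[cut, "stop"] = c[cut]
        df.loc[cut, "to"] = CENSORED
        df.loc[cut, "status"] = 0
    df["Z"] = z[df["id"].to_numpy()].astype(float)
    return df.sort_values(["id", "start"], kind="stable").reset_index(drop=True)


def simulate_subject(cfg: ScenarioConfig, arm: int, frailty: float,
                     rng: np.random.Generator) -> list[TransitionRecord]:
    """Event list for a single subject with a given arm and frailty draw."""
    df = _simulate_cohort(cfg, np.array([arm]), np.array([float(frailty)]), rng)
    return [TransitionRecord("s0", int(r["from"]), int(r["to"]),
                             float(r["start"]), float(r["stop"]),
                             int(r["status"]), {"Z": float(r["Z"])})
            for _, r in df.iterrows()]


def _rep_rng(cfg: ScenarioConfig, rep: int) -> np.random.Generator:
    code = (100 + int(cfg.scenario.split("-")[1]) if cfg.scenario.startswith("alt-")
            else int(cfg.scenario))
    return np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed), code, int(rep)]))


def simulate_dataset(cfg: ScenarioConfig, rep: int = 0,
                     validate: bool = True) -> EventHistory:
    """One replicated trial dataset; reproducible from (config seed, scenario, rep)."""
    rng = _rep_rng(cfg, rep)
    frailty = (rng.gamma(cfg.frailty.shape, cfg.frailty.scale, cfg.n_subjects)
               if cfg.frailty.enabled else np.ones(cfg.n_subjects))
    z = np.zeros(cfg.n_subjects, dtype=int)
    z[rng.permutation(cfg.n_subjects)[:cfg.n_treated]] = 1
    df = _simulate_cohort(cfg, z, frailty, rng)
    return EventHistory(df, structure=cfg.structure, validate=validate)
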