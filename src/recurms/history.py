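"""Multistate event histories in counting-process format.

The observational unit is a *transition record*: subject ``i`` was in
``from_state`` over the half-open interval ``(start, stop]`` and at
``stop`` either moved to ``to_state`` (``status = 1``) or was
right-censored (``status = 0``).  A subject's ordered records form their
observed multistate path.

Two structures are supported for heart-failure-style data:

* ``"illness-death"`` — three states: 0 = alive at home, 1 = in
  hospital, 2 = dead (absorbing), with recovery 1 -> 0 allowed;
* ``"progressive"`` — the same record set viewed with states indexed by
  the cumulative number of prior hospital stays (R1, H1, R2, H2, ..., D),
  so hazards may depend on the event count while staying Markov.

Both views are projections of one record set: progressive labels are
derived from the running count of completed hospital stays, never stored.

Times are days since randomization (time origin 0).  Risk sets use the
left-limit (predictable) convention: a subject transitioning out of a
state at ``t`` is still at risk in that state at ``t``.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stepfun import StepFunction

#: Internal code for the censoring marker in the ``to`` column.
CENSORED = -1

#: State codes for the illness-death model with recovery.
HOME, HOSPITAL, DEAD = 0, 1, 2

_ALLOWED = {(HOME, HOSPITAL), (HOME, DEAD), (HOSPITAL, HOME), (HOSPITAL, DEAD)}
_STRUCTURES = ("illness-death", "progressive")

_COLUMNS = ["id", "from", "to", "start", "stop", "status"]


class HistoryError(ValueError):
    """A collection of transition records violates the data model."""


@dataclass(frozen=True)
class TransitionRecord:
    """One counting-process row: subject in ``from_state`` on ``(start, stop]``."""

    subject_id: object
    from_state: int
    to_state: int
    start: float
    stop: float
    status: int = 1
    covariates: Mapping[str, float] = field(default_factory=dict)


def _parse_state(label) -> int:
    """Map a state label ({0,1,2}, {R1,H1,...,D} or 'cens') to the internal code."""
    s = str(label).strip()
    if s in {"cens", "censored", str(CENSORED)}:
        return CENSORED
    if re.fullmatch(r"R\d+", s):
        return HOME
    if re.fullmatch(r"H\d+", s):
        return HOSPITAL
    if s in {"D", "death"}:
        return DEAD
    try:
        code = int(float(s))
    except ValueError as exc:
        raise HistoryError(f"unknown state label {label!r}") from exc
    if code not in (HOME, HOSPITAL, DEAD, CENSORED):
        raise HistoryError(f"unknown state label {label!r}")
    return code


class EventHistory:
    """A validated collection of subjects' multistate paths.

    Parameters
    ----------
    table : DataFrame
        Columns ``id, from, to, start, stop, status`` plus covariate
        columns (at minimum the treatment indicator ``Z``).
    structure : str
        ``"illness-death"`` or ``"progressive"``.
    validate : bool
        Skip validation only on trusted internal paths.
    """

    def __init__(self, table: pd.DataFrame, structure: str = "illness-death",
                 validate: bool = True):
        if structure not in _STRUCTURES:
            raise HistoryError(f"unknown structure {structure!r}")
        missing = [c for c in _COLUMNS if c not in table.columns]
        if missing:
            raise HistoryError(f"missing columns: {missing}")
        table = table.sort_values(["id", "start"], kind="stable").reset_index(drop=True)
        self.table = table
        self.structure = structure
        if validate:
            self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[TransitionRecord],
                     structure: str = "illness-death") -> "EventHistory":
        records = list(records)
        cov_names: list[str] = []
        for r in records:
            for k in r.covariates:
                if k not in cov_names:
                    cov_names.append(k)
        data = {
            "id": [r.subject_id for r in records],
            "from": [r.from_state for r in records],
            "to": [r.to_state for r in records],
            "start": [float(r.start) for r in records],
            "stop": [float(r.stop) for r in records],
            "status": [int(r.status) for r in records],
        }
        for k in cov_names:
            data[k] = [r.covariates.get(k, np.nan) for r in records]
        df = pd.DataFrame(data) if records else pd.DataFrame(
            {c: pd.Series(dtype=float) for c in _COLUMNS})
        return cls(df, structure=structure)

    # -- validation ---------------------------------------------------

    def _validate(self) -> None:
        df = self.table
        if len(df) == 0:
            return
        frm = df["from"].to_numpy(int)
        to = df["to"].to_numpy(int)
        start = df["start"].to_numpy(float)
        stop = df["stop"].to_numpy(float)
        status = df["status"].to_numpy(int)
        ids = df["id"].to_numpy()

        if np.any(start < 0):
            raise HistoryError("negative start time")
        if np.any(start >= stop):
            raise HistoryError("start >= stop (zero-length or reversed sojourn)")
        if np.any((status == 0) != (to == CENSORED)):
            raise HistoryError("status=0 must coincide with the censoring marker")
        observed = status == 1
        pairs = set(zip(frm[observed].tolist(), to[observed].tolist()))
        bad = pairs - _ALLOWED
        if bad:
            raise HistoryError(f"transitions not in allowed set: {sorted(bad)}")
        if not np.all(np.isin(frm, (HOME, HOSPITAL))):
            raise HistoryError("records may only start from a transient state")

        same = ids[1:] == ids[:-1]
        if np.any(same & (start[1:] != stop[:-1])):
            raise HistoryError("non-contiguous intervals within a subject")
        if np.any(same & (frm[1:] != to[:-1])):
            raise HistoryError("from_state does not continue previous to_state")
        # absorbing / censoring records must be terminal for their subject
        terminal = (to == DEAD) | (to == CENSORED)
        if np.any(terminal[:-1] & same):
            raise HistoryError("records after an absorbing event or censoring")

    # -- basic queries ------------------------------------------------

    def __len__(self) -> int:
        return len(self.table)

    @property
    def subject_ids(self) -> np.ndarray:
        return pd.unique(self.table["id"])

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.table.columns if c not in _COLUMNS]

    def risk_set_size(self, state, t: float) -> int:
        """Subjects occupying ``state`` just prior to ``t`` (left limit)."""
        code = _parse_state(state)
        if code == CENSORED:
            raise HistoryError("censoring is not a state")
        df = self.table
        if code == DEAD:
            return int(((df["to"] == DEAD) & (df["stop"] < t)).sum())
        mask = (df["from"] == code) & (df["start"] < t) & (t <= df["stop"])
        return int(mask.sum())

    def _subject_rows(self, subject) -> pd.DataFrame:
        rows = self.table[self.table["id"] == subject]
        if len(rows) == 0:
            raise HistoryError(f"unknown subject {subject!r}")
        return rows

    def count_previous_events(self, subject, t: float) -> int:
        """Completed hospital stays of ``subject`` strictly before ``t``."""
        rows = self._subject_rows(subject)
        self._check_under_observation(rows, t)
        done = (rows["from"] == HOSPITAL) & (rows["to"] == HOME) & (rows["stop"] < t)
        return int(done.sum())

    def entry_time(self, subject, t: float) -> float:
        """Time ``subject`` entered the state occupied at ``t`` (left-limit state)."""
        rows = self._subject_rows(subject)
        self._check_under_observation(rows, t)
        covering = rows[(rows["start"] < t) & (t <= rows["stop"])]
        if len(covering) == 0:          # t before first transition
            return 0.0
        return float(covering["start"].iloc[0])

    @staticmethod
    def _check_under_observation(rows: pd.DataFrame, t: float) -> None:
        # left-limit convention: a subject absorbed/censored exactly at t
        # is still observable "just prior to t"
        if t <= 0 or t > rows["stop"].iloc[-1]:
            raise HistoryError("subject not under observation at t")

    def recurrent_event_counter(self, subject) -> StepFunction:
        """t -> number of completed home->hospital transitions in [0, t]."""
        rows = self._subject_rows(subject)
        adm = np.sort(rows.loc[(rows["from"] == HOME) & (rows["to"] == HOSPITAL),
                               "stop"].to_numpy(float))
        return StepFunction(adm, np.arange(1, adm.size + 1, dtype=float), 0.0)

    # -- derived per-record covariates --------------------------------

    def with_derived(self) -> pd.DataFrame:
        """Table plus ``prev_events`` (completed hospital stays before each
        record's start) and ``entry`` (= record start; records are maximal
        sojourns, so the interval start is the state entry time)."""
        df = self.table.copy()
        discharge = ((df["from"] == HOSPITAL) & (df["to"] == HOME)).to_numpy()
        grp_start = ~(df["id"].to_numpy()[1:] == df["id"].to_numpy()[:-1]) \
            if len(df) > 1 else np.array([], dtype=bool)
        prev = np.zeros(len(df), dtype=int)
        if len(df) > 1:
            cum = np.concatenate(([0], np.cumsum(discharge[:-1])))
            # reset cumulative count at each subject's first record
            first_idx = np.concatenate(([True], grp_start))
            base = np.where(first_idx, cum, 0)
            np.maximum.accumulate(base, out=base)
            prev = cum - base
        df["prev_events"] = prev
        df["entry"] = df["start"]
        return df

    # -- progressive projection ---------------------------------------

    def progressive_labels(self) -> pd.DataFrame:
        """The same records with progressive state labels R1,H1,R2,...,D."""
        df = self.with_derived()
        adm = np.where(df["from"] == HOME, df["prev_events"],
                       df["prev_events"] + 1)  # stays entered so far
        frm = np.where(df["from"] == HOME,
                       "R" + pd.Series(df["prev_events"] + 1).astype(str),
                       "H" + pd.Series(adm).astype(str))
        nxt_home = "R" + pd.Series(adm + 1).astype(str)
        nxt_hosp = "H" + pd.Series(df["prev_events"] + 1).astype(str)
        to = np.select(
            [df["to"] == HOME, df["to"] == HOSPITAL, df["to"] == DEAD],
            [nxt_home, nxt_hosp, "D"], default="cens")
        out = df.copy()
        out["from"], out["to"] = frm, to
        return out.drop(columns=["prev_events", "entry"])

    # -- I/O -----------------------------------------------------------

    def to_csv(self, path_or_buf=None, progressive_labels: bool = False):
        """Write the long-format CSV (``id,from,to,start,stop,status,Z,...``)."""
        if progressive_labels or self.structure == "progressive":
            df = self.progressive_labels()
        else:
            df = self.table.copy()
            df["to"] = np.where(df["status"] == 1, df["to"].astype(str), "cens")
        cols = _COLUMNS + self.covariate_names
        return df[cols].to_csv(path_or_buf, index=False)

    @classmethod
    def read_csv(cls, path_or_buf, structure: str = "illness-death") -> "EventHistory":
        """Read the long format; accepts {0,1,2} and {R1,H1,...,D} labels."""
        df = pd.read_csv(path_or_buf)
        df["from"] = df["from"].map(_parse_state)
        df["to"] = df["to"].map(_parse_state)
        return cls(df, structure=structure)


def validate_history(records, structure: str = "illness-death") -> EventHistory:
    """Validate a collection of :class:`TransitionRecord` (or a DataFrame)."""
    if isinstance(records, pd.DataFrame):
        return EventHistory(records, structure=structure)
    return EventHistory.from_records(records, structure=structure)


def subject_records(subject_id, admissions: Sequence[float],
                    discharges: Sequence[float], terminal: float,
                    died: bool, covariates: Mapping[str, float] | None = None,
                    ) -> list[TransitionRecord]:
    """Counting-process records for one subject given admission/discharge
    times, the death-or-censoring time and a death flag."""
    covariates = dict(covariates or {})
    adm = [float(a) for a in admissions]
    dis = [float(d) for d in discharges]
    if len(dis) not in (len(adm), len(adm) - 1):
        raise HistoryError("admissions/discharges must alternate")
    merged = [t for pair in zip(adm, dis) for t in pair] + adm[len(dis):]
    if any(b <= a for a, b in zip(merged, merged[1:])):
        raise HistoryError("admission/discharge times must strictly alternate")
    if merged and terminal <= merged[-1]:
        raise HistoryError("terminal time before last event time")

    times = [0.0] + merged + [float(terminal)]
    states = []
    for k in range(len(times) - 1):
        states.append(HOME if k % 2 == 0 else HOSPITAL)
    records = []
    for k in range(len(times) - 1):
        last = k == len(times) - 2
        if last:
            to = DEAD if died else CENSORED
            status = 1 if died else 0
        else:
            to = HOSPITAL if states[k] == HOME else HOME
            status = 1
        records.append(TransitionRecord(subject_id, states[k], to,
                                        times[k], times[k + 1], status, covariates))
    return records


def from_event_list(subjects: Iterable[Mapping], structure: str = "illness-death",
                    ) -> EventHistory:
    """Build an :class:`EventHistory` from per-subject event lists.

    Each element needs keys ``id, admissions, discharges, terminal, died``
    and optionally ``covariates`` (a mapping; should include ``Z``).
    """
    records: list[TransitionRecord] = []
    for s in subjects:
        records.extend(subject_records(s["id"], s.get("admissions", ()),
                                       s.get("discharges", ()), s["terminal"],
                                       bool(s["died"]), s.get("covariates")))
    return EventHistory.from_records(records, structure=structure)
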