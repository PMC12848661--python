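"""Markov-property diagnostics via covariate-augmented regression.

The Markov assumption says the home->hospital hazard at time t depends
only on being at home and on t.  It is probed by augmenting the
counting-process long data with a history covariate on each at-home
interval -- the number of previously completed hospital stays, or the
entry time (days) into the current at-home spell -- and Wald-testing
that covariate in an Andersen-Gill (illness-death view) or
Prentice-Williams-Peterson (progressive view) fit.
"""

from __future__ import annotations

import pandas as pd

from .history import HOME, HOSPITAL, EventHistory

#: history covariate kinds
PREV_COUNT = "prev_count"
ENTRY_TIME = "entry_time"

_KIND_COLUMN = {PREV_COUNT: "prev_events", ENTRY_TIME: "entry"}


def hospitalization_long_data(history: EventHistory) -> pd.DataFrame:
    """At-home risk intervals for the home->hospital cause-specific analysis.

    Hospitalized subjects are not at risk for hospitalization, so
    in-hospital intervals are excluded; death or censoring closes an
    interval without an event.  Carries ``prev_events`` (completed
    hospital stays before the interval) for PWP strata and the Markov
    count covariate, and ``entry`` (interval start = entry time into the
    current at-home spell) for the Markov entry-time covariate.
    """
    df = history.with_derived()
    home = df[df["from"] == HOME].copy()
    home["event"] = ((home["to"] == HOSPITAL) & (home["status"] == 1)).astype(int)
    cols = ["id", "start", "stop", "event", "prev_events", "entry"]
    cols += [c for c in history.covariate_names]
    return home[cols].reset_index(drop=True)


def augment_markov_covariate(history: EventHistory, kind: str) -> pd.DataFrame:
    """Long data with the requested Markov-test covariate attached."""
    if kind not in _KIND_COLUMN:
        raise ValueError(f"unknown Markov covariate kind {kind!r}; "
                         f"use {sorted(_KIND_COLUMN)}")
    return hospitalization_long_data(history)


def markov_covariate_column(kind: str) -> str:
    return _KIND_COLUMN[kind]
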