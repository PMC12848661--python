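"""Build and query multistate event histories.

A subject's follow-up is a path through {0 = at home, 1 = in hospital,
2 = dead}; we store it as counting-process records (from, to, start,
stop, status) and ask risk-set and history questions.
"""

import io

from recurms import EventHistory, from_event_list

history = from_event_list([
    # two hospital stays; the second ends in death on day 60
    {"id": "pat-1", "admissions": [10, 50], "discharges": [15],
     "terminal": 60, "died": True, "covariates": {"Z": 1}},
    # never hospitalized, censored at day 100
    {"id": "pat-2", "admissions": [], "discharges": [], "terminal": 100,
     "died": False, "covariates": {"Z": 0}},
])

print(history.table.to_string(index=False))
print()
print("subjects:", history.n_subjects)
print("in hospital just prior to day 15:", history.risk_set_size(1, 15))
print("in hospital just after day 15:  ", history.risk_set_size(1, 15.001))
print("pat-1 completed stays before day 55:",
      history.count_previous_events("pat-1", 55))
print("pat-1 entered current state (hospital) on day:",
      history.entry_time("pat-1", 55))

text = history.to_csv()
again = EventHistory.read_csv(io.StringIO(text))
print("CSV round trip is exact:", again.table.equals(history.table))
# The left-limit convention means a subject leaving a state at t still
# counts in that state's risk set at t - exactly what hazard estimators
# need for their denominators.
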