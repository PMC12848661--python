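import dataclasses

import numpy as np
import pytest

from recurms import from_event_list, get_scenario, simulate_dataset
from recurms.simulate import CensoringSpec


@pytest.fixture(scope="session")
def toy_history():
    """Two subjects: one with two hospital stays and death, one censored."""
    return from_event_list([
        {"id": "a", "admissions": [10, 50], "discharges": [15], "terminal": 60,
         "died": True, "covariates": {"Z": 1}},
        {"id": "b", "admissions": [], "discharges": [], "terminal": 100,
         "died": False, "covariates": {"Z": 0}},
    ])


def no_censoring_config(n_subjects=80, seed=3, scenario=1):
    """Scenario config whose censoring is pushed beyond any event time."""
    cfg = get_scenario(scenario, n_subjects=n_subjects,
                       n_treated=n_subjects // 2, seed=seed)
    return dataclasses.replace(cfg, censoring=CensoringSpec(mode="random",
                                                            rate=1e-12))


@pytest.fixture(scope="session")
def uncensored_history():
    """Fully observed illness-death cohort (everyone followed to death)."""
    return simulate_dataset(no_censoring_config(), 0)


@pytest.fixture(scope="session")
def scenario1_dataset():
    return simulate_dataset(get_scenario(1, seed=42), 0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
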