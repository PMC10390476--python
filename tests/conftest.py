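import warnings

import numpy as np
import pandas as pd
import pytest

import tolnorm as tn
from tolnorm.glm import Term


@pytest.fixture(scope="session")
def default_table():
    """One synthetic experiment at the default (study-calibrated) truth."""
    table, truth = tn.simulate_experiment(tn.GenerativeParams(), seed=11)
    return table, truth


@pytest.fixture()
def tiny_table():
    """Hand-built 8-row table: 2 replicates x 2 blood x day 1/3, no noise."""
    rows = []
    for rep in (1, 2):
        for blood in (0, 1):
            for day in (1, 3):
                rows.append({"replicate": rep, "day": day, "blood": blood,
                             "sucrose": 0, "alive": 10 + blood, "dead": 5 + day,
                             "load_cfu": 10.0 ** (2 + blood + 0.5 * day)})
    return tn.from_dataframe(pd.DataFrame(rows), load_transform="log10p1")


@pytest.fixture(autouse=True)
def _quiet_separation():
    """Small grouped fixtures legitimately warn; keep test output clean."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", tn.SeparationWarning)
        yield


def make_terms(*specs):
    """Terms from strings like 'Blood:BacterialLoad'."""
    return [Term(s.split(":")) for s in specs]


@pytest.fixture(scope="session")
def null_params():
    """Generator parameters with every treatment effect switched off."""
    surv = {k: 0.0 for k in tn.simulate.DEFAULT_SURVIVAL_COEF}
    surv["Intercept"] = 1.0
    load = {"Intercept": 3.0, "Day": 0.0, "Sucrose": 0.0, "Blood@Day1": 0.0}
    return tn.GenerativeParams(load_coef=load, survival_coef=surv)
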