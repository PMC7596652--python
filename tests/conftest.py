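import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import fifascore as fs

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260)


@pytest.fixture
def small_cohort():
    """A deterministic 60-patient cohort with the default signal structure."""
    return fs.simulate_cohort(n_patients=60, seed=7, missing_rate=0.0)


@pytest.fixture
def weekly_outcomes(small_cohort):
    weekly, _ = fs.aggregate_weekly_frame(small_cohort.daily)
    return weekly, small_cohort.outcomes


def published_cohort_arrays():
    """Ordinal frailty totals and deaths of the 50-patient study cohort.

    Stage sizes 11/10/21/8 (scores 0-3) with 0/0/1/2 in-hospital deaths:
    published group counts used as test inputs.
    """
    totals = np.array([0] * 11 + [1] * 10 + [2] * 21 + [3] * 8, dtype=float)
    deaths = np.zeros(50, dtype=bool)
    deaths[21] = True          # one death among the 21 moderate patients
    deaths[42:44] = True       # two deaths among the 8 severe patients
    return totals, deaths


@pytest.fixture
def published_counts():
    return published_cohort_arrays()


def make_profile(patient_id="P1", **values):
    vals = {p: None for p in fs.Parameter}
    for k, v in values.items():
        vals[fs.Parameter(k)] = v
    return fs.WeeklyProfile(patient_id=patient_id, n_days_used=7, values=vals)
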