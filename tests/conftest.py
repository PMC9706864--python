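import numpy as np
import pandas as pd
import pytest

from ccwdtr import synthetic as syn
from ccwdtr.followup import build_followup


@pytest.fixture(scope="session")
def small_params():
    return syn.default_scenario(n_patients=600, seed=20240901)


@pytest.fixture(scope="session")
def small_cohort(small_params):
    return syn.generate_cohort(small_params)


@pytest.fixture(scope="session")
def small_fu(small_cohort):
    baseline, person_days = small_cohort
    return build_followup(baseline, person_days)


@pytest.fixture(scope="session")
def medium_params():
    return syn.default_scenario(n_patients=2000, seed=777)


@pytest.fixture(scope="session")
def medium_cohort(medium_params):
    return syn.generate_cohort(medium_params)


@pytest.fixture(scope="session")
def medium_fu(medium_cohort):
    baseline, person_days = medium_cohort
    return build_followup(baseline, person_days)


def random_survival_table(rng, n=30, horizon=12, p_death=0.06, p_censor_end=True):
    """Small single-event dataset in long clone-day format (no competing event)."""
    rows = []
    for pid in range(n):
        for day in range(horizon):
            dead = rng.random() < p_death
            rows.append({"patient_id": pid, "day": day, "event": "death" if dead else "none"})
            if dead:
                break
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(99)
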