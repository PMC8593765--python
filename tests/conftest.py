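"""Shared fixtures: scaled-down synthetic surveys and processed stages.

Heavy objects are session-scoped so the generator and processing stages
run once; tests that need different generator settings build their own
configs (cheap at reduced household counts).
"""

import numpy as np
import pandas as pd
import pytest

from censusmrp import (
    SimConfig,
    build_reference_population,
    build_strata,
    census_weights,
    simulate_survey,
    to_tables,
)


@pytest.fixture(scope="session")
def small_config():
    """Default study conditions at a reduced household count."""
    return SimConfig(n_households=1500, seed=42)


@pytest.fixture(scope="session")
def small_pop(small_config):
    return simulate_survey(small_config)


@pytest.fixture(scope="session")
def small_tables(small_pop):
    return to_tables(small_pop)


@pytest.fixture(scope="session")
def small_ref(small_tables):
    return build_reference_population(
        small_tables["census"], small_tables["round1"],
        small_tables["round2"])


@pytest.fixture(scope="session")
def small_cells(small_ref):
    return build_strata(small_ref)


@pytest.fixture(scope="session")
def small_weights(small_tables):
    return census_weights(small_tables["census"])


def toy_round_frame(rows):
    """Build a round CSV-shaped frame from record dicts."""
    cols = ["record_type", "household_id", "reached", "person_id", "name",
            "age", "sex", "member_status", "entry_month",
            "reporting_household", "death_month", "cause", "injury",
            "consulted_doctor", "died_in_hospital", "symptoms"]
    df = pd.DataFrame(rows)
    for c in cols:
        if c not in df.columns:
            df[c] = ""
    return df[cols]


def reach_rows(household_ids, reached=True):
    return [{"record_type": "reach", "household_id": h,
             "reached": int(reached)} for h in household_ids]


def death_row(household, name, age, month, cause="other", injury=False,
              consulted=True, hospital=False, sex="male", symptoms=""):
    return {"record_type": "death", "reporting_household": household,
            "household_id": "", "name": name, "age": age,
            "death_month": month, "cause": cause, "injury": injury,
            "consulted_doctor": consulted, "died_in_hospital": hospital,
            "sex": sex, "symptoms": symptoms}


def member_row(household, person_id, name, age, status, entry_month="",
               sex="female"):
    return {"record_type": "member", "household_id": household,
            "person_id": person_id, "name": name, "age": age, "sex": sex,
            "member_status": status, "entry_month": entry_month}


def toy_census(n=10, households=None, age=30, education=1):
    households = households or [i // 2 for i in range(n)]
    return pd.DataFrame({
        "household_id": households,
        "person_id": list(range(n)),
        "name": [f"Census-{i:03d}" for i in range(n)],
        "age": [age] * n,
        "sex": ["male" if i % 2 else "female" for i in range(n)],
        "education": [education] * n,
    })


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
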