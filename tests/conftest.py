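import numpy as np
import pandas as pd
import pytest

import healthscopes as hs


@pytest.fixture(scope="session")
def small_cfg():
    return hs.SyntheticConfig(n_persons=4000, seed=11)


@pytest.fixture(scope="session")
def small_pop(small_cfg):
    pop = hs.generate_population(small_cfg)
    hs.generate_followup(pop, small_cfg)
    return pop


@pytest.fixture(scope="session")
def small_features(small_pop):
    base = hs.apply_exclusions(small_pop.persons, small_pop.year)
    return hs.assemble_person_year(
        base, small_pop.conditions, small_pop.programs, small_pop.encounters
    )


@pytest.fixture(scope="session")
def small_assignments(small_features):
    return hs.classify_population(small_features)


@pytest.fixture(scope="session")
def small_cohort(small_pop, small_features, small_assignments):
    died = small_features.loc[small_features["died_in_year"], "person_id"]
    return hs.build_cohort(small_assignments, small_pop.followup, died_in_index_year=died)


def make_features_row(**overrides):
    """A fully-false feature row; tests flip the flags they care about."""
    row = {
        "person_id": "X",
        "year": 2016,
        "age": 40,
        "age_band": "adult",
        "died_in_year": False,
        "palliative_referral": False,
        "frail_ltc": False,
        "transitional_need": False,
        "has_cancer": False,
        "has_mental_health": False,
        "n_chronic": 0,
        "complex_chronic": False,
        "simple_chronic": False,
        "chas_blue": False,
        "rental_housing": False,
        "obesity_history": False,
        "lives_alone": False,
        "gender": "female",
        "ethnicity": "Chinese",
        "housing": "private",
        "chas_tier": "none",
        "pioneer_generation": False,
        "region": "Central",
    }
    row.update(overrides)
    return row
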