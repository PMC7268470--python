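import numpy as np
import pandas as pd
import pytest

from colddeck import StudyConfig, generate_donor_pool, generate_recipient_cohort


@pytest.fixture
def config():
    return StudyConfig(
        behaviours=("smoking", "binge"),
        lag_years=5,
        age_group_shift=1,
        repetitions=3,
        seed=11,
    )


def strata_frame(rows):
    """Build a strata-spec DataFrame from (age, gender, ms, race, region, year,
    n, extra...) dicts with defaults filled in."""
    defaults = {
        "age_group": "60-64",
        "gender": "male",
        "marital_status": "married",
        "race": "white",
        "region": "iowa",
        "year": 2010,
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])


@pytest.fixture
def small_strata():
    """Two recipient strata whose lag-shifted donor strata are well stocked."""
    return strata_frame(
        [
            {"age_group": "60-64", "year": 2010, "n": 30},
            {"age_group": "70-74", "gender": "female", "year": 2012, "n": 20},
        ]
    )


@pytest.fixture
def donor_strata():
    """Donor strata matching small_strata after the 5-year / one-band shift."""
    return strata_frame(
        [
            {"age_group": "55-59", "year": 2005, "n": 200, "smoking": 0.3,
             "binge": 0.1},
            {"age_group": "65-69", "gender": "female", "year": 2007, "n": 150,
             "smoking": 0.2, "binge": 0.05},
        ]
    )


@pytest.fixture
def recipients(small_strata):
    return generate_recipient_cohort(small_strata, seed=5, death_rate=0.5)


@pytest.fixture
def donors(donor_strata):
    return generate_donor_pool(donor_strata, missing_rate=0.0, seed=6)
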