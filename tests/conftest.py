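import numpy as np
import pandas as pd
import pytest

from agepath import cohort


@pytest.fixture(scope="session")
def small_cohort():
    """2,000-participant default-calibration cohort, shared across tests."""
    cfg = cohort.default_config(n_participants=2000, seed=42)
    return cohort.generate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_cohort():
    """Cohort with no injected missingness (complete covariates)."""
    cfg = cohort.default_config(n_participants=1500, seed=43, missingness_rates={})
    return cohort.generate_cohort(cfg)


@pytest.fixture(scope="session")
def big_cohort():
    """20,000-participant cohort without missingness for power-hungry checks."""
    cfg = cohort.default_config(n_participants=20000, seed=17, missingness_rates={})
    return cohort.generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_timeline_table():
    """Hand-written cohort rows covering baseline-prevalent, incident and
    death patterns."""
    return pd.DataFrame({
        "id": [1, 2, 3, 4],
        "chronological_age": [50.0, 50.0, 50.0, 50.0],
        "sex": ["female", "male", "female", "male"],
        "onset_age_physical": [48.0, np.nan, 53.0, np.nan],
        "onset_age_psychological": [53.0, np.nan, np.nan, np.nan],
        "onset_age_cognitive": [np.nan, np.nan, 53.0, np.nan],
        "death_age": [55.0, np.nan, np.nan, 58.0],
        "censor_age": [64.0, 64.0, 64.0, 64.0],
    })
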