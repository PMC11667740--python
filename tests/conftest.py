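import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    """Fresh seeded generator per test."""
    return np.random.default_rng(20240123)


@pytest.fixture(scope="session")
def big_study():
    """One large default-config study shared by calibration-sensitive tests.

    10,000 in-person participants (no web add-on cohort), full battery
    simulation; returned as (cohort profiles, measures DataFrame on the
    analysis scale).
    """
    import pandas as pd

    from audiocog.cohort import CohortConfig, simulate_study
    from audiocog.stats import preprocess

    config = CohortConfig(n_inperson=10_000, n_addon_web=0)
    cohort, rows, _ = simulate_study(config, seed=7)
    measures = preprocess(
        pd.DataFrame(rows), log_columns=["AUM_F", "AUM_A"], z_columns=[]
    )
    return cohort, measures
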