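import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def stature_table():
    from growthscreen.lms import builtin_lms_table

    return builtin_lms_table("stature")


@pytest.fixture(scope="session")
def weight_table():
    from growthscreen.lms import builtin_lms_table

    return builtin_lms_table("weight")


@pytest.fixture(scope="session")
def cohort(stature_table, weight_table):
    """A mid-size simulated cohort shared by read-only tests."""
    from growthscreen.lms import simulate_growth

    return simulate_growth(600, stature_table, weight_table, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
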