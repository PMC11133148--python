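import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tailorfit import (
    Scenario,
    build_population_model,
    simulate_dataset,
    solve_thresholds,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def one_factor_scenario() -> Scenario:
    return Scenario("dim_correct", "ML", 6, 5, "symmetric", 0.6, 500)


@pytest.fixture(scope="session")
def one_factor_data(one_factor_scenario):
    """One accepted ordinal dataset from a one-factor population (N=500)."""
    pm = build_population_model(one_factor_scenario)
    th = solve_thresholds(5, 0.0, -0.8)
    return simulate_dataset(pm, th, 500, 20240, scenario=one_factor_scenario)


@pytest.fixture(scope="session")
def big_one_factor_data():
    """Large-sample dataset (N=2000) for parameter-recovery checks."""
    s = Scenario("dim_correct", "ML", 6, 5, "symmetric", 0.6, 2000)
    pm = build_population_model(s)
    th = solve_thresholds(5, 0.0, -0.8)
    return simulate_dataset(pm, th, 2000, 777, scenario=s)


@pytest.fixture(scope="session")
def two_factor_data():
    """Correlated two-factor dataset (r = .30, N=1000)."""
    s = Scenario("cross_correct", "ML", 6, 5, "symmetric", 0.6, 2000,
                 factor_correlation=0.30)
    pm = build_population_model(s)
    th = solve_thresholds(5, 0.0, -0.8)
    return simulate_dataset(pm, th, 1000, 31, scenario=s)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
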