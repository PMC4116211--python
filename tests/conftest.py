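import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from caffscore import SimulationConfig, simulate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort exercising every rendered format, incl. closed-format cola."""
    return simulate_cohort(SimulationConfig(n=600, seed=11, missingness=0.03))


@pytest.fixture(scope="session")
def noiseless_render_cohort():
    """Cohort rendered without missingness, outliers or closed formats.

    Under these settings the refinement chain should reproduce the
    generator's rendered daily values exactly (up to float round-off).
    """
    config = SimulationConfig(
        n=500, seed=23, missingness=0.0, outlier_rate=0.0, closed_format_time_points=()
    )
    return simulate_cohort(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
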