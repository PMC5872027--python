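import numpy as np
import pytest

from neuronspan import (
    SCENARIOS,
    calibrate_gompertz,
    discretize_to_days,
    generate_cohort,
    sample_lifespans,
)


@pytest.fixture(scope="session")
def wt_gompertz():
    """Wild-type lifespan marginal: mean 10.5 d, CV 0.25."""
    return calibrate_gompertz(10.5, 0.25)


@pytest.fixture(scope="session")
def day_lifespans(wt_gompertz):
    """A fixed day-discretized lifespan sample used as an empirical marginal."""
    return discretize_to_days(sample_lifespans(wt_gompertz, 1000, seed=12345))


@pytest.fixture(scope="session")
def small_cohort():
    """A small wild-type cohort with zero loss/lifespan coupling."""
    return generate_cohort(SCENARIOS["wild_type"], 600, seed=2024)
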