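import numpy as np
import pytest

from skinkipm.synthetic import (
    TruthParams,
    simulate_environment,
    simulate_population,
)


@pytest.fixture(scope="session")
def env_60():
    """A 5-year noisy seasonal environment series."""
    return simulate_environment(60, seed=101)


@pytest.fixture(scope="session")
def small_population(env_60):
    """A modest synthetic population with defaults (detection imperfect)."""
    params = TruthParams(seed=101)
    captures, truth = simulate_population(params, 400, 60, env_60)
    return params, captures, truth


@pytest.fixture(scope="session")
def perfect_detection_population(env_60):
    """Deaths off, detection perfect, no measurement noise: exact-limit data."""
    params = TruthParams(
        seed=55,
        gompertz_b0=-30.0,
        gompertz_b1=0.0,
        beta_phi=(0.0, 0.0, 0.0, 0.0),
        beta_p=(30.0, 0.0, 0.0, 0.0),
        svl_obs_sd=0.0,
        sex_unknown_frac=0.0,
    )
    captures, truth = simulate_population(params, 120, 36, env_60)
    return params, captures, truth
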