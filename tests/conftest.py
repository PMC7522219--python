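import numpy as np
import pytest

from hypothesis import HealthCheck, settings

import lightresponse as lr

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def catalog():
    """Ground-truth simulation specs for both species and all curve families."""
    return lr.fixture_table1()


@pytest.fixture(scope="session")
def soybean_steps():
    return np.asarray(lr.SOYBEAN_STEPS, dtype=float)


@pytest.fixture(scope="session")
def wheat_steps():
    return np.asarray(lr.WHEAT_STEPS, dtype=float)


def random_ye_params(rng, with_rd=False, i_max=2000.0):
    """Draw a physiologically plausible nonasymptotic parameter set whose
    validity window covers the light range."""
    while True:
        alpha = rng.uniform(0.02, 0.3)
        beta = rng.uniform(1e-4, 1e-3)
        gamma = rng.uniform(-1.5e-4, 1.5e-3)
        if beta + gamma < 5e-5:
            continue
        if gamma < 0 and -1.0 / gamma <= 1.1 * i_max:
            continue
        rd = rng.uniform(0.5, 5.0) if with_rd else 0.0
        return lr.YeParams(alpha, beta, gamma, rd)


def random_nh_params(rng, with_rd=False):
    alpha = rng.uniform(0.02, 0.3)
    theta = rng.uniform(0.3, 0.99)
    y_max = rng.uniform(20.0, 400.0)
    rd = rng.uniform(0.5, 5.0) if with_rd else 0.0
    return lr.NHParams(alpha, theta, y_max, rd)
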