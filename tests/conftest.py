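import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import npidce as n

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

#: Published overall mean preference weights (left ASC first, fee last) used
#: as simulation ground truth throughout the suite.
TABLE3_BETA = np.array(
    [-0.08, 0.54, 0.59, -0.89, -0.33, 0.19, -0.05, -0.07, -0.37, 0.10, 0.03, -0.02]
)

#: Published two-class mean patterns (pro-NPI class first).
TABLE4_CLASS1 = np.array(
    [-0.19, 1.98, 1.76, -0.51, 0.18, 0.49, -0.06, 0.21, 0.35, 0.56, -0.02, -0.02]
)
TABLE4_CLASS2 = np.array(
    [0.11, -0.37, 0.04, -1.72, -0.87, -0.08, -0.12, -0.29, -1.01, -0.19, -0.02, -0.04]
)


def sigma_vector(space, value, names=n.DEFAULT_RANDOM_SET):
    s = np.zeros(space.n_predictors)
    for nm in names:
        s[space.predictor_names.index(nm)] = value
    return s


@pytest.fixture(scope="session")
def space():
    return n.AttributeSpace.canonical()


@pytest.fixture(scope="session")
def canonical_design(space):
    return n.generate_design(space, n.DesignDims.for_space(space), seed=1)


@pytest.fixture(scope="session")
def small_design(space):
    dims = n.DesignDims(4, 5, 2, space.max_levels)
    return n.generate_design(space, dims, seed=5, n_iter=1500)


@pytest.fixture(scope="session")
def homogeneous_dataset(space, small_design):
    """150 respondents, sigma = 0 truth: the conditional-logit regime."""
    prof = n.simulate_profiles(150, seed=30)
    cfg = n.SimulationConfig(
        classes=(n.TasteClass(TABLE3_BETA, np.zeros(space.n_predictors)),)
    )
    return n.simulate_choices(small_design, prof, cfg, seed=31)


@pytest.fixture(scope="session")
def heterogeneous_dataset(space, small_design):
    """200 respondents with sigma = 0.8 on the five random predictors."""
    prof = n.simulate_profiles(200, seed=40)
    cfg = n.SimulationConfig(
        classes=(n.TasteClass(TABLE3_BETA, sigma_vector(space, 0.8)),)
    )
    return n.simulate_choices(small_design, prof, cfg, seed=41)
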