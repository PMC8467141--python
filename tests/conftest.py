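import numpy as np
import pytest

from gphurdle.distributions import GPParams
from gphurdle.regression import CountDataset
from gphurdle.simulate import SimScenario, generate

# (mu, alpha) grid spanning under-, equi- and over-dispersion
PARAM_GRID = [
    (0.5, 0.0), (0.5, 0.3), (0.5, 1.0), (0.5, -0.3),
    (1.0, 0.0), (1.0, 0.2), (1.0, 0.8), (1.0, -0.5),
    (2.0, 0.0), (2.0, 0.1), (2.0, 0.5), (2.0, -0.2),
    (5.0, 0.0), (5.0, 0.15), (5.0, 0.4), (5.0, -0.1),
    (10.0, 0.05), (10.0, 0.2), (0.2, 0.5), (8.0, -0.05),
]

NONNEG_ALPHA_GRID = [(m, a) for m, a in PARAM_GRID if a >= 0]


@pytest.fixture(scope="session")
def param_grid():
    return [GPParams(m, a) for m, a in PARAM_GRID]


@pytest.fixture(scope="session")
def nonneg_param_grid():
    return [GPParams(m, a) for m, a in NONNEG_ALPHA_GRID]


# recovery scenario: distinct count/zero covariates, moderate over-dispersion
RECOVERY_TRUTH = np.array([0.2, 0.1, 0.5, 0.4, -0.8])


def recovery_scenario(seed: int, n: int = 2000) -> SimScenario:
    return SimScenario(
        n=n,
        beta=RECOVERY_TRUTH[1:3],
        delta=RECOVERY_TRUTH[3:5],
        alpha=RECOVERY_TRUTH[0],
        covariate_spec=[("a", [0.0, 1.0], [0.5, 0.5]), ("b", [0.0, 1.0], [0.5, 0.5])],
        x_names=["a"],
        z_names=["b"],
        seed=seed,
    )


@pytest.fixture(scope="session")
def recovery_dataset():
    return generate(recovery_scenario(seed=11))


@pytest.fixture()
def tiny_dataset():
    """Six observations, two distinct covariates in each part."""
    x = np.column_stack([np.ones(6), [0, 0, 1, 1, 0, 1]])
    z = np.column_stack([np.ones(6), [1, 0, 1, 0, 1, 0]])
    return CountDataset(np.array([0, 2, 1, 0, 3, 5]), x, z)
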