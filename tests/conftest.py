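import numpy as np
import pytest

from nppvcea import ModelConfig, load_default_parameters


@pytest.fixture(scope="session")
def default_params():
    ps = load_default_parameters()
    ps.validate()
    return ps


@pytest.fixture()
def config():
    return ModelConfig()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_901)


def random_transition_matrix(rng: np.random.Generator) -> np.ndarray:
    """Random row-stochastic 4x4 matrix with an absorbing death row."""
    m = np.zeros((4, 4))
    for i in range(3):
        m[i] = rng.dirichlet(np.ones(4))
    m[3, 3] = 1.0
    return m
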