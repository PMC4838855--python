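import numpy as np
import pytest

from polymsm import (
    LangevinParams,
    build_block_chain,
    build_four_well,
    GroundTruthChain,
)


@pytest.fixture(scope="session")
def four_well():
    return build_four_well()


@pytest.fixture(scope="session")
def block_chain():
    return build_block_chain(seed=0)


@pytest.fixture(scope="session")
def two_state_chain():
    return GroundTruthChain(np.array([[0.9, 0.1], [0.1, 0.9]]))


def random_reversible_chain(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random reversible transition matrix from a symmetric weight matrix."""
    W = rng.uniform(0.1, 1.0, size=(n, n))
    W = (W + W.T) / 2.0
    return W / W.sum(axis=1, keepdims=True)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
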