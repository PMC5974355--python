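import numpy as np
import pytest

from ternergy import ChainConfig, default_truth


@pytest.fixture(scope="session")
def truth():
    """Default synthetic-colony ground truth, fixed seed."""
    return default_truth(seed=11)


@pytest.fixture(scope="session")
def tiny_chains():
    """Very short chains for unit tests of fitting machinery."""
    return ChainConfig(n_chains=3, n_samples=4000, n_burnin=1000, seed=5)


@pytest.fixture(scope="session")
def reduced_chains():
    """The reduced analysis configuration (3 x 20k, 5k burn-in)."""
    return ChainConfig.reduced(seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
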