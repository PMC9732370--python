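import numpy as np
import pytest

from tfdenoise import synthetic


@pytest.fixture(scope="session")
def sim_seed1():
    """Default-condition synthetic block, seed 1 (56 trials, -5 dB SNR)."""
    return synthetic.generate(synthetic.SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_sim():
    """A small 8-trial block for fast end-to-end checks."""
    return synthetic.generate(synthetic.SimConfig(seed=1, n_trials=8))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def corr(a, b):
    return float(np.corrcoef(np.asarray(a).ravel(), np.asarray(b).ravel())[0, 1])
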