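import numpy as np
import pytest

from recnets import EnsembleParams, WeightMatrix, sample_weights


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def zero_matrix():
    """A 10x10 zero coupling matrix (decoupled leaky units)."""
    params = EnsembleParams(N=10, tau=0.0, g=1e-12, seed=0)
    return WeightMatrix(values=np.zeros((10, 10)), params=params)


def draw(N, tau, *, g=None, geff=None, seed=0, realization=0, policy="correlated_gaussian"):
    params = EnsembleParams(N=N, tau=tau, g=g, geff=geff, seed=seed,
                            diagonal_policy=policy)
    return sample_weights(params, realization_index=realization)


@pytest.fixture
def draw_weights():
    return draw
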