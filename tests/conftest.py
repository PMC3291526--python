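import numpy as np
import pytest

from rstdp import (LIFConfig, LinearRuleSpec, LinearStimulus, NetworkMatrices,
                   StimulusEnsemble, build_input_correlation,
                   generate_bottom_up_matrix)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_240_901)


@pytest.fixture(scope="session")
def Q20():
    """Well-conditioned 20x20 bottom-up matrix (smoothed draw)."""
    return generate_bottom_up_matrix(20, 20, epsilon=0.1, smooth_width=3,
                                     rng=np.random.default_rng(7))


@pytest.fixture(scope="session")
def C20():
    return build_input_correlation(20, np.random.default_rng(11))


@pytest.fixture
def small_net(rng):
    Q = generate_bottom_up_matrix(4, 4, rng=np.random.default_rng(3))
    W = 0.01 * np.random.default_rng(4).standard_normal((4, 4))
    return NetworkMatrices(Q, W)
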