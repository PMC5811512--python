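import numpy as np
import pytest

from openblock import RateSet


def random_rates(rng, m=1, low=-1.5, high=1.5, gamma_positive=True):
    """Log-uniform random rate set in 10**[low, high] per rate."""
    a, b, g, d = 10.0 ** rng.uniform(low, high, size=4)
    if not gamma_positive:
        g = 0.0
    return RateSet(float(a), float(b), float(g), float(d), m)


@pytest.fixture
def rng():
    return np.random.default_rng(20180209)


@pytest.fixture
def worked_example():
    """The 3-state set (alpha, beta, gamma, delta) = (3, 0, 1, 1), whose
    waveform is O(t) = (1 + 3 exp(-2t) - 4 exp(-3t)) / 2 with peak at
    t_p = ln 2, O_p = 0.625, psi = 0.25, O_ss = 0.5."""
    return RateSet(3.0, 0.0, 1.0, 1.0, 1)
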