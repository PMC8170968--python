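import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_spd(rng, d, scale=1.0):
    """A well-conditioned random SPD matrix."""
    A = rng.standard_normal((d, d))
    return scale * (A @ A.T + d * np.eye(d))


@pytest.fixture
def spd_pairs(rng):
    """20 random SPD pairs of assorted sizes."""
    return [
        (random_spd(rng, d), random_spd(rng, d))
        for d in ([2] * 5 + [3] * 5 + [4] * 5 + [6] * 5)
    ]
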