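import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def vonmises_deg(rng, mu_deg, kappa, n):
    """Von Mises sample in degrees on [0, 360)."""
    return np.degrees(rng.vonmises(np.radians(mu_deg), kappa, n)) % 360.0
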