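import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def gaussian_bump(n: int, sigma: float, amplitude: float = 10.0, center=None):
    """Isotropic Gaussian bump on an n x n zero background (1 px sampling)."""
    if center is None:
        center = (n / 2.0, n / 2.0)
    y, x = np.mgrid[0:n, 0:n]
    return amplitude * np.exp(
        -(((x - center[0]) ** 2 + (y - center[1]) ** 2) / (2.0 * sigma**2))
    )


HALF_MAX_AREA = 2.0 * np.pi * np.log(2.0)  # * sigma^2
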