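import numpy as np
import pytest

from radnoise.phantom import ProcessedImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_two_region_image(seed: int, n: int = 128,
                          sigma_left: float = 0.01,
                          sigma_right: float = 0.04):
    """Flat field with two noise regimes: the spatial-adaptivity fixture."""
    gen = np.random.default_rng(seed)
    clean = np.full((n, n), 0.5)
    sigma = np.where(np.arange(n)[None, :] < n // 2, sigma_left, sigma_right)
    sigma = sigma * np.ones((n, n))
    noisy = clean + gen.standard_normal((n, n)) * sigma
    return clean, sigma, ProcessedImage(noisy, (0.0, 0.0, 1.0))


def region_slices(n: int, margin: int = 10, gap: int = 5):
    """Interior slices of the left and right halves, away from the seam."""
    left = (slice(margin, n - margin), slice(margin, n // 2 - gap))
    right = (slice(margin, n - margin), slice(n // 2 + gap, n - margin))
    return left, right
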