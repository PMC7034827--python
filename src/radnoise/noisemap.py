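"""Per-pixel noise estimation and multi-scale noise covariance.

The noise map is a robust per-pixel sigma estimate from the display-domain
image: the image is high-passed by subtracting its 3x3 median (which
suppresses anatomy and edges), and the local median absolute deviation of
that residual, scaled by 1.4826, is corrected by a Monte-Carlo calibrated
gain so it is unbiased for i.i.d. Gaussian noise.

The "multi-scale noise covariance" is the per-level noise variance this
spatial sigma field induces when it passes through the pyramid: per-level
scalar gains are calibrated by pushing unit-variance white noise through
the decomposition, then the sigma^2 map is smoothed/decimated to each
level's geometry and scaled by the level gain.  Covariance is carried as
per-level variance maps (the denoiser consumes only a local sigma), not
full inter-pixel covariance matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .phantom import ProcessedImage
from .pyramid import Pyramid, PyramidSpec, _downsample, decompose

__all__ = [
    "NoiseMap",
    "BandNoiseCov",
    "estimate_noise_map",
    "calibrate_band_gains",
    "propagate_noise_covariance",
]


@dataclass
class NoiseMap:
    """Per-pixel noise standard deviation in display-domain units."""

    sigma: np.ndarray
    window: int
    estimator_tag: str = "median-residual-mad"

    def __post_init__(self) -> None:
        if (self.sigma < 0).any():
            raise ValueError("noise map must be nonnegative")


@dataclass
class BandNoiseCov:
    """Per-pyramid-level noise variance maps plus the calibration gains."""

    level_variance_maps: list[np.ndarray]
    gains: np.ndarray

    def sigma_map(self, level: int) -> np.ndarray:
        return np.sqrt(self.level_variance_maps[level])


# Full-chain calibration gains for the median-residual MAD estimator,
# keyed by window size.  Computed once per process from white noise with a
# fixed internal seed; covers both the high-pass operator's noise gain and
# the finite-window MAD bias.
_ESTIMATOR_GAIN_CACHE: dict[int, float] = {}


def _raw_local_sigma(img: np.ndarray, window: int) -> np.ndarray:
    resid = img - median_filter(img, size=3, mode="reflect")
    med = median_filter(resid, size=window, mode="reflect")
    mad = median_filter(np.abs(resid - med), size=window, mode="reflect")
    return 1.4826 * mad


def _estimator_gain(window: int) -> float:
    gain = _ESTIMATOR_GAIN_CACHE.get(window)
    if gain is None:
        rng = np.random.default_rng(20240901 + window)
        vals = []
        for _ in range(8):
            field = rng.standard_normal((192, 192))
            est = _raw_local_sigma(field, window)
            m = window  # trim the reflective border
            vals.append(np.median(est[m:-m, m:-m]))
        gain = float(np.mean(vals))
        _ESTIMATOR_GAIN_CACHE[window] = gain
    return gain


def estimate_noise_map(img: ProcessedImage | np.ndarray, window: int = 7) -> NoiseMap:
    """Estimate local noise sigma of a display-domain image.

    Parameters
    ----------
    img : ProcessedImage or 2D array
    window : odd int >= 3
        Side of the local MAD window, in pixels.
    """
    pixels = img.pixels if isinstance(img, ProcessedImage) else np.asarray(img, float)
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if window > min(pixels.shape):
        raise ValueError(
            f"window {window} larger than image {pixels.shape}"
        )
    sigma = _raw_local_sigma(pixels, window) / _estimator_gain(window)
    return NoiseMap(sigma=sigma, window=window)


# In-memory gain cache keyed by (spec key, n_mc, seed).
_BAND_GAIN_CACHE: dict[tuple[str, int, int], np.ndarray] = {}


def calibrate_band_gains(spec: PyramidSpec, n_mc: int = 50, seed: int = 7,
                         size: int = 128) -> np.ndarray:
    """Monte-Carlo variance gains of each pyramid band for white noise.

    Unit-variance white noise is decomposed ``n_mc`` times; ``gain[l]`` is
    the mean empirical variance of band ``l`` (the residual's gain is
    appended last).  Gains are cached per (spec, n_mc, seed).
    """
    if n_mc < 10:
        raise ValueError("n_mc must be >= 10")
    key = (spec.cache_key(), n_mc, seed)
    cached = _BAND_GAIN_CACHE.get(key)
    if cached is not None:
        return cached
    rng = np.random.default_rng(seed)
    sums = np.zeros(spec.n_levels + 1)
    for _ in range(n_mc):
        p = decompose(rng.standard_normal((size, size)), spec)
        for l, band in enumerate(p.bands):
            m = 8  # trim boundary-affected rim
            core = band[m:-m, m:-m] if min(band.shape) > 2 * m else band
            sums[l] += core.var()
        m = 4
        core = (p.residual[m:-m, m:-m]
                if min(p.residual.shape) > 2 * m else p.residual)
        sums[-1] += core.var()
    gains = sums / n_mc
    _BAND_GAIN_CACHE[key] = gains
    return gains


def propagate_noise_covariance(noise_map: NoiseMap, spec: PyramidSpec,
                               gains: np.ndarray | None = None) -> BandNoiseCov:
    """Propagate a per-pixel sigma map into per-level variance maps.

    Level ``l``'s map is ``gain_l`` times the sigma^2 field smoothed and
    decimated to level-l geometry with the pyramid's own low-pass chain.
    Exactly homogeneous of degree 2 in sigma.
    """
    if gains is None:
        gains = calibrate_band_gains(spec)
    if len(gains) < spec.n_levels:
        raise ValueError("need one gain per pyramid level")
    var = noise_map.sigma.astype(np.float64) ** 2
    maps: list[np.ndarray] = []
    for level in range(spec.n_levels):
        maps.append(np.clip(gains[level] * var, 0.0, None))
        var = _downsample(var, spec)
    return BandNoiseCov(level_variance_maps=maps, gains=np.asarray(gains, float))


def band_cov_for_pyramid(noise_map: NoiseMap, pyr: Pyramid,
                         gains: np.ndarray | None = None) -> BandNoiseCov:
    """Convenience: covariance with shapes checked against ``pyr``."""
    cov = propagate_noise_covariance(noise_map, pyr.spec, gains)
    for m, band in zip(cov.level_variance_maps, pyr.bands):
        if m.shape != band.shape:
            raise ValueError("covariance/pyramid shape mismatch")
    return cov
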