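"""Multi-scale Laplacian decomposition with exact reconstruction.

The multi-scale frequency backbone shared by both denoising engines.  A
Laplacian pyramid is used rather than a wavelet transform: retaining the
intermediate low-pass images makes the inverse exact by construction
(``G_l = band_l + upsample(G_{l+1})``), so the perfect-reconstruction
contract holds to floating-point precision for any analysis kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate1d

__all__ = ["PyramidSpec", "Pyramid", "decompose", "reconstruct"]

#: 5-tap binomial low-pass, the classic Burt-Adelson generating kernel.
BINOMIAL5 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


@dataclass(frozen=True)
class PyramidSpec:
    """Parameters of the multi-scale decomposition.

    Attributes
    ----------
    n_levels : int
        Number of detail (band-pass) levels; the residual low-pass sits
        below the coarsest band.
    analysis_kernel : tuple of float
        1D separable low-pass coefficients, normalized to sum 1.
    boundary : str
        Boundary rule for filtering; ``"reflect"`` mirrors about the edge
        pixel (scipy convention).
    """

    n_levels: int = 4
    analysis_kernel: tuple[float, ...] = tuple(BINOMIAL5)
    boundary: str = "reflect"

    def __post_init__(self) -> None:
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        k = np.asarray(self.analysis_kernel, dtype=float)
        if k.ndim != 1 or k.size < 3:
            raise ValueError("analysis_kernel must be a 1D kernel of >= 3 taps")
        if abs(k.sum() - 1.0) > 1e-9:
            raise ValueError("analysis_kernel must be normalized to sum 1")

    @property
    def kernel(self) -> np.ndarray:
        return np.asarray(self.analysis_kernel, dtype=float)

    def cache_key(self) -> str:
        """Stable string key identifying this spec (used for gain caches)."""
        taps = ",".join(f"{c:.12g}" for c in self.analysis_kernel)
        return f"L{self.n_levels}|k[{taps}]|{self.boundary}"


@dataclass
class Pyramid:
    """Band decomposition of an image, finest detail first.

    ``bands[l]`` has the spatial shape of the l-th low-pass image; the
    ``residual`` is the coarsest low-pass.  ``reconstruct`` inverts
    ``decompose`` exactly.
    """

    bands: list[np.ndarray]
    residual: np.ndarray
    spec: PyramidSpec
    shapes: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_levels(self) -> int:
        return len(self.bands)


def _smooth(img: np.ndarray, spec: PyramidSpec) -> np.ndarray:
    k = spec.kernel
    out = correlate1d(img, k, axis=0, mode=spec.boundary)
    out = correlate1d(out, k, axis=1, mode=spec.boundary)
    return out


def _downsample(img: np.ndarray, spec: PyramidSpec) -> np.ndarray:
    return _smooth(img, spec)[::2, ::2]


def _upsample(img: np.ndarray, shape: tuple[int, int], spec: PyramidSpec) -> np.ndarray:
    """Zero-insert to ``shape`` then low-pass with 2x the analysis kernel.

    The coarse grid is reflect-padded *before* zero-insertion so boundary
    taps fall on real samples, not inserted zeros: a constant image then
    upsamples to the same constant everywhere, edges included.
    """
    pad = (len(spec.kernel) // 2 + 1) // 2 + 1
    coarse = np.pad(img, pad, mode="reflect")
    up = np.zeros((2 * coarse.shape[0], 2 * coarse.shape[1]), dtype=img.dtype)
    up[::2, ::2] = coarse
    k = 2.0 * spec.kernel
    up = correlate1d(up, k, axis=0, mode="constant")
    up = correlate1d(up, k, axis=1, mode="constant")
    off = 2 * pad
    return up[off:off + shape[0], off:off + shape[1]]


def decompose(img: np.ndarray, spec: PyramidSpec | None = None) -> Pyramid:
    """Split an image into ``n_levels`` detail bands plus a low-pass residual.

    band_l = G_l - upsample(G_{l+1}), residual = G_{n_levels}, where G_0 is
    the input and G_{l+1} = downsample(smooth(G_l)).

    Raises
    ------
    ValueError
        If the image is too small for the requested number of levels (the
        message names the limiting level).
    """
    spec = spec or PyramidSpec()
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2D image")
    g = img
    bands: list[np.ndarray] = []
    shapes: list[tuple[int, int]] = []
    for level in range(spec.n_levels):
        if min(g.shape) < 4:
            raise ValueError(
                f"image too small to decompose at level {level}: "
                f"low-pass shape {g.shape} (need >= 4 per side)"
            )
        g_next = _downsample(g, spec)
        bands.append(g - _upsample(g_next, g.shape, spec))
        shapes.append(g.shape)
        g = g_next
    return Pyramid(bands=bands, residual=g, spec=spec, shapes=shapes)


def reconstruct(p: Pyramid) -> np.ndarray:
    """Exact inverse of :func:`decompose` (same upsampler, same boundary)."""
    if len(p.bands) != len(p.shapes):
        raise ValueError("pyramid bands/shapes inconsistent")
    g = p.residual
    for band, shape in zip(reversed(p.bands), reversed(p.shapes)):
        if band.shape != shape:
            raise ValueError(
                f"band shape {band.shape} does not match recorded {shape}"
            )
        g = band + _upsample(g, shape, p.spec)
    return g
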