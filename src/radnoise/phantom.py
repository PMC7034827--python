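"""Synthetic chest-radiograph phantoms and dose-dependent acquisition.

Stands in for a clinical posteroanterior chest image set: a stylized
anatomy (elliptical lung fields, sinusoidal rib bands, branching vessel
trees, heart/mediastinum shading, optional nodules, consolidations and
interstitial texture) rendered as a strictly positive linear-detector
signal, plus a mixed Poisson-Gaussian acquisition model in which quantum
noise scales inversely with the dose fraction.

Realism is deliberately limited to the *presence and geometry* of the
structures a reader would score (lucent lung, vessels, rib edges, heart
border, retrocardiac detail): the phantom exists so that edge-, blob- and
texture-preservation of the denoising engines can be measured against a
known ground truth, not to fool a radiologist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "PhantomConfig",
    "AcquisitionConfig",
    "GroundTruthImage",
    "RawImage",
    "ProcessedImage",
    "generate_phantom",
    "simulate_acquisition",
    "normalize_raw",
    "preprocess",
    "invert_preprocess",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and contrast of the synthetic chest phantom.

    Signal levels are relative linear-domain transmissions in (0, 1]:
    lung fields transmit most (bright on the raw detector image), the
    mediastinum/heart least.  All lesion contrasts are in [0, 1] and act
    multiplicatively (signal * (1 - contrast) at lesion center).
    """

    image_size: int = 512
    lung_attenuation: float = 0.85
    mediastinum_attenuation: float = 0.25
    body_attenuation: float = 0.45
    n_ribs: int = 8
    rib_contrast: float = 0.15
    n_vessel_trees: int = 4
    vessel_contrast: float = 0.12
    # (center_yx in fractional coords, radius px, contrast)
    nodules: tuple[tuple[tuple[float, float], float, float], ...] = ()
    # (polygon vertices in fractional coords, contrast)
    consolidation_regions: tuple[tuple[tuple[tuple[float, float], ...], float], ...] = ()
    interstitial_texture_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lung_attenuation", "mediastinum_attenuation", "body_attenuation"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for _, radius, contrast in self.nodules:
            if not 0.0 <= contrast <= 1.0:
                raise ValueError("nodule contrast must be in [0, 1]")
            if radius <= 0:
                raise ValueError("nodule radius must be positive")
        for _, contrast in self.consolidation_regions:
            if not 0.0 <= contrast <= 1.0:
                raise ValueError("consolidation contrast must be in [0, 1]")
        if not 0.0 <= self.rib_contrast <= 1.0:
            raise ValueError("rib_contrast must be in [0, 1]")
        if not 0.0 <= self.vessel_contrast <= 1.0:
            raise ValueError("vessel_contrast must be in [0, 1]")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Dose-dependent acquisition model.

    The expected photon count per pixel is ``dose_fraction *
    baseline_quanta_per_pixel * signal`` after scatter blur; a Poisson
    sample of that, scaled by the detector gain, plus zero-mean Gaussian
    electronic noise, is recorded.  ``dose_fraction`` is relative to the
    baseline arm (the clinical arms used 0.6, 0.5 and 0.4).
    """

    dose_fraction: float = 1.0
    baseline_quanta_per_pixel: float = 5000.0
    electronic_sigma: float = 2.0
    scatter_blur_sigma: float = 2.0
    detector_gain: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dose_fraction <= 0:
            raise ValueError("dose_fraction must be > 0")
        if self.electronic_sigma < 0:
            raise ValueError("electronic_sigma must be >= 0")
        if self.baseline_quanta_per_pixel <= 0:
            raise ValueError("baseline_quanta_per_pixel must be > 0")


@dataclass
class GroundTruthImage:
    """Noise-free linear-domain expected signal plus structure masks."""

    image: np.ndarray
    masks: dict[str, np.ndarray]
    config: PhantomConfig


@dataclass
class RawImage:
    """Noisy linear-detector counts from one simulated exposure."""

    pixels: np.ndarray
    dose_fraction: float
    provenance: dict = field(default_factory=dict)


@dataclass
class ProcessedImage:
    """Display-domain image in [0, 1] with the invertible log-window params.

    ``transform_params = (offset, lo, window)``: pixel = (log(raw + offset)
    - lo) / window.
    """

    pixels: np.ndarray
    transform_params: tuple[float, float, float]


def _ellipse_mask(shape: tuple[int, int], cy: float, cx: float,
                  ry: float, rx: float, tilt: float = 0.0) -> np.ndarray:
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    y = (yy - cy) / ry
    x = (xx - cx) / rx
    if tilt:
        c, s = math.cos(tilt), math.sin(tilt)
        y, x = c * y - s * x, s * y + c * x
    return y * y + x * x <= 1.0


def _polygon_mask(shape: tuple[int, int], verts: np.ndarray) -> np.ndarray:
    from skimage.draw import polygon

    rr, cc = polygon(verts[:, 0], verts[:, 1], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def _vessel_tree(rng: np.random.Generator, mask: np.ndarray, start: tuple[float, float],
                 direction: float, length: int, width: float, depth: int = 0) -> None:
    """Random branching walk painting a vessel into ``mask`` (in place)."""
    n = mask.shape[0]
    y, x = start
    ang = direction
    for _ in range(length):
        ang += rng.normal(0.0, 0.08)
        y += math.sin(ang)
        x += math.cos(ang)
        if not (0 <= y < n and 0 <= x < n):
            return
        r = max(1, int(round(width)))
        y0, y1 = max(0, int(y) - r), min(n, int(y) + r + 1)
        x0, x1 = max(0, int(x) - r), min(n, int(x) + r + 1)
        mask[y0:y1, x0:x1] = True
    if depth < 3 and width > 1.0:
        for sign in (-1.0, 1.0):
            _vessel_tree(rng, mask, (y, x), ang + sign * rng.uniform(0.3, 0.7),
                         int(length * 0.7), width * 0.6, depth + 1)


def generate_phantom(config: PhantomConfig) -> GroundTruthImage:
    """Render the noise-free phantom for ``config``.

    Deterministic for a fixed ``(config, seed)``.  Raises ``ValueError``
    with a diagnostic if a configured nodule would fall outside the image.
    """
    n = config.image_size
    shape = (n, n)
    rng = np.random.default_rng(config.seed)

    img = np.full(shape, config.body_attenuation, dtype=np.float64)
    masks: dict[str, np.ndarray] = {}

    # Lung fields: two tilted ellipses left/right of the midline.
    lungs = np.zeros(shape, dtype=bool)
    for side in (-1.0, 1.0):
        lungs |= _ellipse_mask(shape, cy=0.52 * n, cx=(0.5 + side * 0.22) * n,
                               ry=0.34 * n, rx=0.16 * n, tilt=side * 0.12)
    img[lungs] = config.lung_attenuation
    masks["lung"] = lungs

    # Heart / mediastinum: central ellipse shifted left-low, dominates lungs
    # where it overlaps (retrocardiac area keeps a dimmer copy of vessels).
    heart = _ellipse_mask(shape, cy=0.62 * n, cx=0.46 * n, ry=0.22 * n, rx=0.17 * n)
    img[heart] = config.mediastinum_attenuation
    masks["mediastinum"] = heart

    # Ribs: sinusoidal bands of reduced transmission across the lung fields.
    ribs = np.zeros(shape, dtype=bool)
    if config.n_ribs > 0:
        yy, xx = np.mgrid[0:n, 0:n].astype(float)
        spacing = 0.75 * n / max(config.n_ribs, 1)
        phase = yy + 0.09 * n * np.sin(2.0 * math.pi * xx / n) - 0.12 * n
        band = np.mod(phase, spacing) < 0.22 * spacing
        ribs = band & lungs
        img[ribs] *= 1.0 - config.rib_contrast
    masks["rib"] = ribs

    # Vessel trees: branching walks from the hilum into each lung.
    vessels = np.zeros(shape, dtype=bool)
    for t in range(config.n_vessel_trees):
        side = -1.0 if t % 2 == 0 else 1.0
        start = (0.45 * n + rng.uniform(-0.05, 0.05) * n,
                 (0.5 + side * 0.08) * n)
        direction = side * rng.uniform(0.1, 0.6) + (math.pi if side < 0 else 0.0)
        _vessel_tree(rng, vessels, start, direction,
                     length=int(0.3 * n), width=2.2)
    vessels &= lungs | heart
    img[vessels & ~heart] *= 1.0 - config.vessel_contrast
    img[vessels & heart] *= 1.0 - 0.5 * config.vessel_contrast
    masks["vessel"] = vessels

    # Nodules: smooth radial blobs of configured radius and contrast.
    nodule_mask = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    for (fy, fx), radius, contrast in config.nodules:
        cy, cx = fy * n, fx * n
        if not (radius <= cy <= n - 1 - radius and radius <= cx <= n - 1 - radius):
            raise ValueError(
                f"nodule at ({fy:.3f}, {fx:.3f}) with radius {radius} px "
                f"falls outside the {n}x{n} image"
            )
        r2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / radius**2
        profile = np.clip(1.0 - r2, 0.0, None)  # parabolic cap, support = radius
        img *= 1.0 - contrast * profile
        nodule_mask |= r2 <= 1.0
    masks["nodule"] = nodule_mask

    # Consolidations: polygonal patches of reduced transmission.
    consol = np.zeros(shape, dtype=bool)
    for verts_frac, contrast in config.consolidation_regions:
        verts = np.asarray(verts_frac, dtype=float) * n
        if verts.min() < 0 or verts.max() > n - 1:
            raise ValueError("consolidation polygon extends outside the image")
        m = _polygon_mask(shape, verts)
        img[m] *= 1.0 - contrast
        consol |= m
    masks["consolidation"] = consol

    # Interstitial texture: band-pass random field inside the lungs.
    if config.interstitial_texture_amplitude > 0:
        noise = rng.standard_normal(shape)
        tex = gaussian_filter(noise, 1.5) - gaussian_filter(noise, 4.0)
        tex /= max(np.abs(tex).max(), 1e-12)
        img *= 1.0 + config.interstitial_texture_amplitude * tex * lungs

    img = np.clip(img, 1e-4, None)  # strictly positive ground truth
    return GroundTruthImage(image=img, masks=masks, config=config)


def simulate_acquisition(truth: GroundTruthImage | np.ndarray,
                         acq: AcquisitionConfig) -> RawImage:
    """Simulate one exposure of ``truth`` at ``acq.dose_fraction``.

    pixel = gain * Poisson(dose_fraction * quanta * blur(truth))
            + Normal(0, electronic_sigma)

    so quantum noise variance in the dose-normalized image scales as
    1 / dose_fraction.
    """
    signal = truth.image if isinstance(truth, GroundTruthImage) else np.asarray(truth, float)
    if signal.min() <= 0:
        raise ValueError("ground truth must be strictly positive")
    rng = np.random.default_rng(acq.seed)
    if acq.scatter_blur_sigma > 0:
        signal = gaussian_filter(signal, acq.scatter_blur_sigma)
    lam = acq.dose_fraction * acq.baseline_quanta_per_pixel * signal
    counts = rng.poisson(lam).astype(np.float64) * acq.detector_gain
    if acq.electronic_sigma > 0:
        counts += rng.normal(0.0, acq.electronic_sigma, size=signal.shape)
    prov = {
        "dose_fraction": acq.dose_fraction,
        "acq_seed": acq.seed,
        "phantom_seed": truth.config.seed if isinstance(truth, GroundTruthImage) else None,
    }
    return RawImage(pixels=counts, dose_fraction=acq.dose_fraction, provenance=prov)


def normalize_raw(raw: RawImage, acq: AcquisitionConfig) -> np.ndarray:
    """Dose-normalize counts back to the truth's signal scale."""
    denom = acq.detector_gain * acq.baseline_quanta_per_pixel * raw.dose_fraction
    return raw.pixels / denom


def preprocess(raw: RawImage | np.ndarray) -> ProcessedImage:
    """Log transform + min-max windowing into the display domain [0, 1].

    The transform parameters ``(offset, lo, window)`` are recorded so the
    mapping is exactly invertible (:func:`invert_preprocess`).  The offset
    is 0 for strictly positive counts and 1 otherwise (guards ``log(0)``).
    """
    pixels = raw.pixels if isinstance(raw, RawImage) else np.asarray(raw, float)
    if pixels.min() < 0:
        pixels = np.clip(pixels, 0.0, None)
    if pixels.max() == 0:
        raise ValueError("cannot window an all-zero image")
    offset = 0.0 if pixels.min() > 0 else 1.0
    logged = np.log(pixels + offset)
    lo, hi = float(logged.min()), float(logged.max())
    window = hi - lo
    if window == 0.0:
        window = 1.0  # constant image maps to constant 0
    out = (logged - lo) / window
    return ProcessedImage(pixels=out, transform_params=(offset, lo, window))


def invert_preprocess(img: ProcessedImage) -> np.ndarray:
    """Exact inverse of :func:`preprocess` given the recorded parameters."""
    offset, lo, window = img.transform_params
    return np.exp(img.pixels * window + lo) - offset


def clean_display(truth: GroundTruthImage, acq: AcquisitionConfig,
                  reference: ProcessedImage) -> np.ndarray:
    """Noise-free display-domain image under ``reference``'s transform.

    Maps the expected detector counts (scatter-blurred truth times dose and
    gain, no sampling noise) through the log-window transform recorded on a
    processed acquisition, giving the ground truth against which denoised
    outputs can be compared in the display domain.
    """
    signal = truth.image
    if acq.scatter_blur_sigma > 0:
        signal = gaussian_filter(signal, acq.scatter_blur_sigma)
    lam = (acq.detector_gain * acq.dose_fraction
           * acq.baseline_quanta_per_pixel * signal)
    offset, lo, window = reference.transform_params
    return (np.log(lam + offset) - lo) / window
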