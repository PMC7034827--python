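"""Image I/O: 16-bit grayscale TIFF/PNG and monochrome DICOM.

Display-domain images live in [0, 1] 32/64-bit float internally and are
re-quantized only at export; the 16-bit export scaling is recorded in the
returned metadata so round trips are exact at the integer level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["LoadedImage", "read_image", "write_image"]


@dataclass
class LoadedImage:
    pixels: np.ndarray
    bit_depth: int
    domain: str  # "raw" (linear counts) or "display"
    provenance: dict = field(default_factory=dict)


def read_image(path: str | Path, domain: str = "raw") -> LoadedImage:
    """Read a 16-bit grayscale TIFF/PNG or a monochrome DICOM file.

    DICOM pixel data are rescaled through the stored slope/intercept.
    RGB inputs are rejected; 8-bit inputs are accepted but flagged in the
    provenance as upcast.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    prov: dict = {"path": str(path)}
    if suffix in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(path)
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = slope * arr + intercept
        if arr.ndim != 2:
            raise ValueError("only monochrome 2D DICOM is supported")
        prov.update(rescale_slope=slope, rescale_intercept=intercept)
        return LoadedImage(pixels=arr, bit_depth=int(ds.BitsStored),
                           domain=domain, provenance=prov)
    if suffix in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    elif suffix == ".png":
        import imageio.v3 as iio

        arr = iio.imread(path)
    else:
        raise ValueError(f"unsupported image format: {suffix}")
    if arr.ndim == 3:
        raise ValueError("RGB/multichannel input is not supported; "
                         "expected single-channel grayscale")
    if arr.dtype == np.uint8:
        prov["upcast_from_8bit"] = True
        bit_depth = 8
    elif arr.dtype == np.uint16:
        bit_depth = 16
    else:
        bit_depth = arr.dtype.itemsize * 8
    return LoadedImage(pixels=arr.astype(np.float64), bit_depth=bit_depth,
                       domain=domain, provenance=prov)


def write_image(path: str | Path, pixels: np.ndarray,
                scale_to_uint16: bool = False) -> dict:
    """Write a 2D array as 16-bit TIFF/PNG (or 32-bit float TIFF).

    With ``scale_to_uint16`` the [min, max] range is mapped onto 0..65535
    and the scaling returned for the provenance record; integer inputs
    are written bit-exactly.
    """
    path = Path(path)
    pixels = np.asarray(pixels)
    meta: dict = {"path": str(path)}
    if scale_to_uint16:
        lo, hi = float(pixels.min()), float(pixels.max())
        scale = 65535.0 / (hi - lo) if hi > lo else 1.0
        out = np.round((pixels - lo) * scale).astype(np.uint16)
        meta.update(export_offset=lo, export_scale=scale)
    else:
        out = pixels if pixels.dtype in (np.uint8, np.uint16) \
            else pixels.astype(np.float32)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, out)
    elif suffix == ".png":
        import imageio.v3 as iio

        if out.dtype not in (np.uint8, np.uint16):
            raise ValueError("PNG export requires uint8/uint16 "
                             "(use scale_to_uint16=True)")
        iio.imwrite(path, out)
    else:
        raise ValueError(f"unsupported image format: {suffix}")
    return meta
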