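"""Reading and writing CT slices.

DICOM slices are rescaled (slope/intercept), optionally windowed, and
affinely mapped to [0, 1]; grey PNGs are divided by their bit-depth
maximum. Masks and processed images are written back as 8- or 16-bit
grey PNG.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
from PIL import Image

from adipoct.core import GreyImage, RegionMask

log = logging.getLogger(__name__)


class UnsupportedFormatError(ValueError):
    """File is readable but not a format this package handles."""


def _minmax_map(values: np.ndarray, low: float, high: float) -> np.ndarray:
    """Clip to [low, high] then map affinely onto [0, 1].

    A degenerate window (high <= low) collapses to a constant 0 image.
    """
    if high <= low:
        return np.zeros_like(values, dtype=np.float64)
    clipped = np.clip(values.astype(np.float64), low, high)
    return (clipped - low) / (high - low)


def read_dicom(path: str | Path, window: tuple[float, float] | None = None) -> GreyImage:
    """Read a single-frame grey-scale DICOM slice as a [0, 1] image.

    Stored values are rescaled by the file's RescaleSlope/Intercept if
    present, clipped to ``window`` (default: the slice's own min/max),
    then affinely mapped to [0, 1].
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    if int(getattr(ds, "NumberOfFrames", 1)) > 1:
        raise UnsupportedFormatError(f"{path}: multi-frame DICOM not supported")
    if int(getattr(ds, "SamplesPerPixel", 1)) != 1:
        raise UnsupportedFormatError(f"{path}: colour DICOM not supported")
    raw = ds.pixel_array.astype(np.float64)
    if raw.ndim != 2:
        raise UnsupportedFormatError(f"{path}: expected a 2-D pixel grid")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    values = raw * slope + intercept
    if window is None:
        low, high = float(values.min()), float(values.max())
    else:
        low, high = float(window[0]), float(window[1])
    return GreyImage(_minmax_map(values, low, high), source_id=str(path))


def read_png(path: str | Path) -> GreyImage:
    """Read an 8- or 16-bit grey-scale PNG as a [0, 1] image.

    RGB input is converted by luminance with a logged warning; palette
    PNGs are rejected.
    """
    img = Image.open(str(path))
    if img.mode == "P":
        raise UnsupportedFormatError(f"{path}: palette PNG not supported")
    if img.mode in ("RGB", "RGBA"):
        log.warning("%s: RGB PNG converted to grey scale by luminance", path)
        img = img.convert("L")
    if img.mode == "L":
        maxval = 255.0
    elif img.mode in ("I", "I;16", "I;16B"):
        maxval = 65535.0
    else:
        raise UnsupportedFormatError(f"{path}: unsupported PNG mode {img.mode}")
    arr = np.asarray(img, dtype=np.float64)
    return GreyImage(arr / maxval, source_id=str(path))


def write_png(image: GreyImage, path: str | Path, bit_depth: int = 8) -> Path:
    """Quantise to ``bit_depth`` (8 or 16) and write a grey PNG."""
    if bit_depth not in (8, 16):
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    maxval = 2**bit_depth - 1
    quantised = np.rint(image.pixels * maxval)
    if bit_depth == 8:
        pil = Image.fromarray(quantised.astype(np.uint8), mode="L")
    else:
        pil = Image.fromarray(quantised.astype(np.uint32), mode="I").convert("I;16")
    path = Path(path)
    pil.save(str(path))
    return path


def write_mask_png(mask: RegionMask, path: str | Path) -> Path:
    """Write a boolean mask as an 8-bit 0/255 PNG."""
    pil = Image.fromarray(np.where(mask.bits, 255, 0).astype(np.uint8), mode="L")
    path = Path(path)
    pil.save(str(path))
    return path


def read_image(path: str | Path, window: tuple[float, float] | None = None) -> GreyImage:
    """Dispatch on extension: ``.dcm`` -> DICOM, anything else -> PNG."""
    p = Path(path)
    if p.suffix.lower() in (".dcm", ".dicom"):
        return read_dicom(p, window=window)
    return read_png(p)
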