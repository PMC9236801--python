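"""Core pixel containers shared by every pipeline stage.

All intensities live on a unitless [0, 1] grey scale regardless of the
source modality; pixels are addressed (row, col), 0-based, row 0 at the
top of the image. A pixel is *background* (air) iff its value is at or
below ``BACKGROUND_TOL`` — min–max normalisation sends true air to
exactly 0 only in the ideal case, so a small tolerance is required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Default intensity at or below which a pixel counts as background.
BACKGROUND_TOL = 0.02

#: Minimum image side length (required for scale-space construction).
MIN_SIDE = 16


class DegenerateInputError(ValueError):
    """Raised when an input is too uniform/empty for the operation."""


@dataclass
class GreyImage:
    """A single grey-scale slice with intensities in [0, 1].

    Parameters
    ----------
    pixels
        2-D float array; every value must satisfy ``0 <= v <= 1``.
    source_id
        Free-text provenance tag (file path, phantom spec hash, ...).
    """

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D grid, got ndim={self.pixels.ndim}")
        h, w = self.pixels.shape
        if h < MIN_SIDE or w < MIN_SIDE:
            raise ValueError(
                f"image {h}x{w} smaller than minimum {MIN_SIDE}x{MIN_SIDE}"
            )
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < 0.0 or hi > 1.0:
            raise ValueError(f"intensities outside [0,1]: min={lo}, max={hi}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def foreground(self, background_tol: float = BACKGROUND_TOL) -> np.ndarray:
        """Boolean grid of non-background pixels (``v > background_tol``)."""
        return self.pixels > background_tol

    def with_pixels(self, pixels: np.ndarray, suffix: str = "") -> "GreyImage":
        return GreyImage(pixels, source_id=self.source_id + suffix)


@dataclass
class RegionMask:
    """Boolean grid marking one segmented region of a parent image."""

    bits: np.ndarray
    label: str = "region"

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.ndim != 2:
            raise ValueError("mask must be a 2-D boolean grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.bits.shape

    @property
    def count(self) -> int:
        return int(self.bits.sum())

    def __and__(self, other: "RegionMask") -> "RegionMask":
        return RegionMask(self.bits & other.bits, f"{self.label}&{other.label}")

    def disjoint(self, other: "RegionMask") -> bool:
        return not np.any(self.bits & other.bits)


def dice(a: RegionMask | np.ndarray, b: RegionMask | np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    abits = a.bits if isinstance(a, RegionMask) else np.asarray(a, bool)
    bbits = b.bits if isinstance(b, RegionMask) else np.asarray(b, bool)
    if abits.shape != bbits.shape:
        raise ValueError("mask shapes differ")
    denom = int(abits.sum()) + int(bbits.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((abits & bbits).sum()) / denom
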