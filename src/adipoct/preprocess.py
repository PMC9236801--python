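"""Bed-board detection and exclusion.

The scanner couch appears near the bottom of an axial slice and must be
excluded before segmentation. The body dominates the non-background
pixel profile: rows crossing the subject carry many more non-background
pixels than rows crossing only the couch, so low-count rows inside a
bottom search band mark the obstacle. Removal is tied to 4-connected
components so that rows shared between couch and body never lose
subject pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from adipoct.core import BACKGROUND_TOL, GreyImage, RegionMask


@dataclass
class ProfilePair:
    """Per-row and per-column counts of non-background pixels."""

    row_counts: np.ndarray
    col_counts: np.ndarray
    background_tol: float


def compute_profiles(image: GreyImage,
                     background_tol: float = BACKGROUND_TOL) -> ProfilePair:
    """Count non-background pixels along each row and each column."""
    fg = image.foreground(background_tol)
    return ProfilePair(
        row_counts=fg.sum(axis=1).astype(np.int64),
        col_counts=fg.sum(axis=0).astype(np.int64),
        background_tol=background_tol,
    )


def remove_bed(image: GreyImage, profile_frac: float = 0.5,
               search_band: float = 0.25,
               background_tol: float = BACKGROUND_TOL,
               ) -> tuple[GreyImage, RegionMask]:
    """Zero the bed-board structure; return (cleaned image, removed mask).

    Rows inside the bottom ``search_band`` fraction of the frame whose
    non-background count falls below ``profile_frac`` × the maximum row
    count are classified bed rows. Every 4-connected non-background
    component that touches a bed row — except the largest component,
    the subject — is zeroed. Idempotent: a second application removes
    nothing.

    Row counts are taken on a 3×3 median-filtered copy so isolated
    noise specks in the air do not inflate the profile; the removal
    itself operates on the raw pixels.
    """
    if not 0.0 < profile_frac < 1.0:
        raise ValueError("profile_frac must lie in (0, 1)")
    h, w = image.shape
    fg = image.foreground(background_tol)
    if not fg.any():
        return image, RegionMask(np.zeros((h, w), bool), "bed_board")

    smoothed = ndimage.median_filter(image.pixels, size=3)
    row_counts = (smoothed > background_tol).sum(axis=1)
    cutoff = profile_frac * row_counts.max()
    band_start = h - int(round(search_band * h))
    bed_rows = np.zeros(h, dtype=bool)
    bed_rows[band_start:] = row_counts[band_start:] < cutoff

    labels, n = ndimage.label(fg, structure=np.array([[0, 1, 0],
                                                      [1, 1, 1],
                                                      [0, 1, 0]]))
    removed = np.zeros((h, w), dtype=bool)
    if n > 0:
        sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
        largest = int(np.argmax(sizes)) + 1
        touching = np.unique(labels[bed_rows, :])
        for lab in touching:
            if lab != 0 and lab != largest:
                removed |= labels == lab

    cleaned = image.pixels.copy()
    cleaned[removed] = 0.0
    return (image.with_pixels(cleaned, "|bed_removed"),
            RegionMask(removed, "bed_board"))
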