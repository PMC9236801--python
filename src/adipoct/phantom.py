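"""Synthetic abdominal-slice phantom with exact ground truth.

The phantom emulates the scene every stage of the pipeline must cope
with on a real axial abdominal CT slice: an elliptical body
cross-section on an air background, a thin skin band, a hypodense
subcutaneous-fat ring between skin and fascia, a brighter
visceral/organ interior, a scanner-couch ("bed board") strip near the
bottom of the frame, and additive Gaussian noise. Region masks are the
exact noise-free label sets, so segmentation accuracy can be graded
without clinical data.

Intensity defaults put fat as a distinct mid-dark band, hypodense to
soft tissue as on CT, with all values inside [0, 1]; they are fixture
conventions, not calibrated Hounsfield physics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from adipoct.core import GreyImage, RegionMask


class InvalidSpecError(ValueError):
    """Phantom geometry that clips the frame or violates an invariant."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensities and noise level of one synthetic slice.

    ``body_axes`` are the (semi-axis-rows, semi-axis-cols) of the outer
    body ellipse in pixels; the subcutaneous ring sits between the skin
    band (outermost ``skin_thickness`` pixels of the body) and the
    visceral interior. The bed board is a horizontal strip of width
    ``bed_width_frac`` × image width, centred, disjoint from the body —
    narrower than the body diameter so that, as on real scans, body
    rows carry more non-background pixels than bed rows.

    Real abdominal outlines are lumpy, not perfect ellipses, and that
    lumpiness is what makes one subject's slices recognisable among
    another's. ``wobble_amp`` (fractional radius) and ``wobble_waves``
    (highest harmonic) add a smooth subject-specific radial
    perturbation, and ``n_islands`` elliptical visceral-fat islands
    (grey value ``intensity_fat``, as on CT) are scattered inside the
    visceral compartment. Both are drawn from ``shape_seed`` — the
    "anatomy" seed, kept separate from ``rng_seed`` (the
    acquisition-noise seed) so the same subject can be imaged
    repeatedly with fresh noise. Islands never touch the subcutaneous
    ring, so its ground-truth mask is unaffected.
    """

    height: int = 128
    width: int = 128
    body_axes: tuple[float, float] = (45.0, 55.0)
    body_center: tuple[float, float] | None = None
    skin_thickness: float = 2.0
    fat_ring_thickness: float = 10.0
    wobble_amp: float = 0.05
    wobble_waves: int = 8
    n_islands: int = 24
    island_radius: tuple[float, float] = (2.0, 5.0)
    shape_seed: int = 0
    intensity_skin: float = 0.55
    intensity_fat: float = 0.35
    intensity_viscera: float = 0.65
    intensity_bed: float = 0.80
    bed_row_start: int = 112
    bed_thickness: int = 6
    bed_width_frac: float = 0.4
    noise_sd: float = 0.02
    rng_seed: int = 0

    @property
    def center(self) -> tuple[float, float]:
        if self.body_center is not None:
            return self.body_center
        # body sits slightly above frame centre to leave room for the bed
        return ((self.height - 1) / 2.0 - 6.0, (self.width - 1) / 2.0)

    def validate(self) -> None:
        a, b = self.body_axes
        cr, cc = self.center
        if self.fat_ring_thickness < 2:
            raise InvalidSpecError("fat_ring_thickness must be >= 2 px")
        if self.skin_thickness < 1:
            raise InvalidSpecError("skin_thickness must be >= 1 px")
        if not 0.0 <= self.wobble_amp < 0.2:
            raise InvalidSpecError("wobble_amp must lie in [0, 0.2)")
        if a - self.skin_thickness - self.fat_ring_thickness <= 2:
            raise InvalidSpecError("viscera core vanishes: axes too small for ring")
        amax, bmax = a * (1 + self.wobble_amp), b * (1 + self.wobble_amp)
        if (cr - amax < 4 or cc - bmax < 4
                or cr + amax > self.height - 5 or cc + bmax > self.width - 5):
            raise InvalidSpecError("body outline must fit with a 4-pixel margin")
        if self.bed_thickness > 0:
            if self.bed_row_start <= cr + amax:
                raise InvalidSpecError("bed strip overlaps the body ellipse")
            if self.bed_row_start + self.bed_thickness > self.height:
                raise InvalidSpecError("bed strip clips the frame bottom")
        for name in ("intensity_skin", "intensity_fat", "intensity_viscera",
                     "intensity_bed"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise InvalidSpecError(f"{name}={v} outside (0, 1]")
        # contrast assumption of the region-growing criterion
        for other in (self.intensity_viscera, self.intensity_skin):
            if abs(self.intensity_fat - other) < 3 * self.noise_sd:
                raise InvalidSpecError(
                    "fat intensity within 3*noise_sd of a neighbouring class")


@dataclass
class PhantomTruth:
    """A generated slice plus its exact noise-free region masks."""

    image: GreyImage
    mask_subcut: RegionMask
    mask_viscera: RegionMask
    mask_bed: RegionMask
    spec: PhantomSpec


def _wobble(phi: np.ndarray, amp: float, waves: int, shape_seed: int) -> np.ndarray:
    """Smooth periodic radial perturbation with max amplitude ``amp``."""
    if amp == 0.0 or waves < 2:
        return np.zeros_like(phi)
    rng = np.random.default_rng(shape_seed)
    w = np.zeros_like(phi)
    for k in range(2, waves + 1):
        w += rng.normal() / k * np.cos(k * phi + rng.uniform(0, TWO_PI))
    peak = np.abs(w).max()
    return w * (amp / peak) if peak > 0 else w


TWO_PI = 2.0 * np.pi


def make_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Render the phantom scene; deterministic for fixed seeds."""
    spec.validate()
    shape = (spec.height, spec.width)
    a, b = spec.body_axes
    c = spec.center
    ts, tf = spec.skin_thickness, spec.fat_ring_thickness

    rr, cc = np.indices(shape, dtype=np.float64)
    dr, dc = rr - c[0], cc - c[1]
    dist = np.hypot(dr, dc)
    phi = np.arctan2(dr, dc)
    # ellipse radius at each polar angle, then the subject-specific lumps
    r_e = 1.0 / np.sqrt((np.cos(phi) / b) ** 2 + (np.sin(phi) / a) ** 2)
    boundary = r_e * (1.0 + _wobble(phi, spec.wobble_amp, spec.wobble_waves,
                                    spec.shape_seed))
    body = dist <= boundary
    inner_skin = dist <= boundary - ts
    inner_fat = dist <= boundary - ts - tf
    skin = body & ~inner_skin
    fat = inner_skin & ~inner_fat
    viscera = inner_fat

    # visceral-fat islands: same grey value as subcutaneous fat, strictly
    # interior to the visceral compartment (never touching the ring)
    islands = np.zeros(shape, dtype=bool)
    if spec.n_islands > 0:
        srng = np.random.default_rng(spec.shape_seed + 1)
        rmin, rmax = spec.island_radius
        placed = 0
        for _ in range(20 * spec.n_islands):
            if placed >= spec.n_islands:
                break
            pr = srng.uniform(0, spec.height)
            pc = srng.uniform(0, spec.width)
            ra = srng.uniform(rmin, rmax)
            rb = srng.uniform(rmin, rmax)
            ang = float(np.arctan2(pr - c[0], pc - c[1]))
            r_here = (1.0 / np.sqrt((np.cos(ang) / b) ** 2
                                    + (np.sin(ang) / a) ** 2))
            limit = r_here * (1 - spec.wobble_amp) - ts - tf - max(ra, rb) - 3
            if np.hypot(pr - c[0], pc - c[1]) > limit:
                continue
            blob = (((rr - pr) / ra) ** 2 + ((cc - pc) / rb) ** 2) <= 1.0
            islands |= blob
            placed += 1
        islands &= inner_fat

    bed = np.zeros(shape, dtype=bool)
    if spec.bed_thickness > 0:
        half = spec.bed_width_frac * spec.width / 2.0
        c0 = int(np.ceil((spec.width - 1) / 2.0 - half))
        c1 = int(np.floor((spec.width - 1) / 2.0 + half)) + 1
        bed[spec.bed_row_start:spec.bed_row_start + spec.bed_thickness, c0:c1] = True

    scene = np.zeros(shape, dtype=np.float64)
    scene[skin] = spec.intensity_skin
    scene[fat] = spec.intensity_fat
    scene[viscera] = spec.intensity_viscera
    scene[islands] = spec.intensity_fat
    scene[bed] = spec.intensity_bed

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed)
        scene = scene + rng.normal(0.0, spec.noise_sd, size=shape)
    pixels = np.clip(scene, 0.0, 1.0)

    image = GreyImage(pixels, source_id=f"phantom(seed={spec.rng_seed})")
    return PhantomTruth(
        image=image,
        mask_subcut=RegionMask(fat, "subcutaneous_fat"),
        mask_viscera=RegionMask(viscera, "viscera"),
        mask_bed=RegionMask(bed, "bed_board"),
        spec=spec,
    )


def _rotmat(rotation_deg: float) -> np.ndarray:
    th = np.deg2rad(rotation_deg)
    # rotation in (row, col) coordinates; positive angle turns the +row
    # axis toward the +col axis
    return np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])


def transform(image: GreyImage, rotation_deg: float = 0.0, scale: float = 1.0,
              crop: tuple[int, int, int, int] | None = None):
    """Rotate/scale about the image centre, then optionally crop.

    Bilinear resampling; out-of-frame pixels are filled with 0. ``crop``
    is ``(row0, col0, height, width)`` applied after the warp.

    Returns ``(GreyImage, forward_map)`` where ``forward_map`` sends an
    (N, 2) array of source (row, col) points to their output positions,
    for validating feature matches against known geometry.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    h, w = image.shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    rot = _rotmat(rotation_deg)

    if crop is not None:
        r0, c0, ch, cw = crop
        if ch <= 0 or cw <= 0:
            raise ValueError("empty crop rectangle")
        if r0 < 0 or c0 < 0 or r0 + ch > h or c0 + cw > w:
            raise ValueError("crop outside image bounds")
        offset = np.array([r0, c0], dtype=np.float64)
        out_shape = (ch, cw)
    else:
        offset = np.zeros(2)
        out_shape = (h, w)

    # inverse map: output lattice -> source coordinates
    rr, cc = np.indices(out_shape, dtype=np.float64)
    pts_out = np.stack([rr.ravel(), cc.ravel()]) + offset[:, None]
    pts_in = rot.T @ ((pts_out - center[:, None]) / scale) + center[:, None]
    warped = ndimage.map_coordinates(image.pixels, pts_in, order=1, mode="constant",
                                     cval=0.0).reshape(out_shape)
    warped = np.clip(warped, 0.0, 1.0)

    def forward_map(points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return (scale * (rot @ (pts.T - center[:, None])) + center[:, None]).T \
            - offset

    out = GreyImage(warped, source_id=image.source_id
                    + f"|rot{rotation_deg}|s{scale}"
                    + (f"|crop{crop}" if crop else ""))
    return out, forward_map
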