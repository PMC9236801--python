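"""Scale-invariant feature transform, implemented from scratch.

The stages follow the classical recipe: a Gaussian scale-space pyramid
(octaves × intervals) and its difference-of-Gaussians (DoG)
counterpart; 26-neighbour extremum detection; subpixel refinement by a
second-order Taylor fit with contrast and edge-response culling;
orientation assignment from a 36-bin (10°) gradient histogram; and
4×4×8 = 128-component gradient descriptors rotated to the main
orientation, normalised, clipped at 0.2 and renormalised.

Coordinate and angle conventions: pixels are (row, col) with row 0 at
the top; orientations are measured counter-clockwise from the +x
(column) axis, i.e. the usual mathematical angle with the y axis
pointing up the image. The input is not upsampled before the first
octave, so the base octave works at native resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from adipoct.core import GreyImage

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class SiftConfig:
    """All tunables of the keypoint pipeline.

    n_intervals
        Scales per octave at which extrema are sought (s); each octave
        holds s+3 Gaussian and s+2 DoG layers.
    sigma0
        Base scale of the first layer (1.6, the standard choice).
    contrast_T
        Low-contrast cull: a refined point is dropped when
        ``|D̂| < contrast_T / n_intervals`` (T = 0.04).
    edge_r
        Edge-response cull ratio r: reject when the spatial-Hessian
        trace²/det ≥ (r+1)²/r (r = 10).
    init_blur
        Blur assumed already present in the input image.
    """

    n_intervals: int = 3
    sigma0: float = 1.6
    octaves: int | None = None
    border: int = 5
    contrast_T: float = 0.04
    edge_r: float = 10.0
    max_refine_iter: int = 5
    n_orient_bins: int = 36
    peak_ratio: float = 0.8
    orient_sigma_factor: float = 1.5   # weight sd = 1.5 * keypoint scale
    orient_radius_factor: float = 3.0  # sampling extent = 3 * weight sd
    descr_grid: int = 4                # 4x4 subregions
    descr_bins: int = 8                # 8 orientation bins per subregion
    descr_scale_factor: float = 3.0    # subregion width = 3 * keypoint scale
    descr_clip: float = 0.2
    init_blur: float = 0.5


@dataclass
class ScaleSpace:
    """Gaussian pyramid and its DoG counterpart.

    ``gaussians[o][i]`` has absolute scale sigma0·2^(o + i/s); each
    octave's base is the 2× decimation of the previous octave's layer
    at relative scale 2·sigma0.
    """

    gaussians: list[list[np.ndarray]]
    dogs: list[list[np.ndarray]]
    sigma0: float
    n_intervals: int

    @property
    def n_octaves(self) -> int:
        return len(self.gaussians)

    def sigma_abs(self, octave: int, layer: float) -> float:
        return self.sigma0 * 2.0 ** (octave + layer / self.n_intervals)

    def sigma_rel(self, layer: float) -> float:
        """Octave-relative scale of a (possibly fractional) layer index."""
        return self.sigma0 * 2.0 ** (layer / self.n_intervals)


@dataclass
class Keypoint:
    """A DoG extremum, possibly refined and oriented.

    (row, col) are subpixel coordinates in the base-image frame;
    (r_oct, c_oct) the same point in its octave's frame; ``interval``
    is the (fractional after refinement) DoG layer index.
    """

    row: float
    col: float
    sigma: float
    octave: int
    interval: float
    r_oct: float
    c_oct: float
    response: float = 0.0
    orientation: float | None = None


def gaussian_blur(pixels: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian convolution with replicated borders and a wide kernel.

    The kernel is truncated at 6 sd so that sequential blurs compose
    like the continuous semigroup to well below 1e-6.
    """
    if sigma <= 0:
        return pixels.copy()
    return ndimage.gaussian_filter(pixels, sigma, mode="nearest", truncate=6.0)


def default_octaves(shape: tuple[int, int]) -> int:
    """floor(log2(min dim)) − 3, clamped so the top octave is ≥ 8×8."""
    m = min(shape)
    n = int(math.floor(math.log2(m))) - 3
    while n > 1 and m / 2 ** (n - 1) < 8:
        n -= 1
    return max(n, 1)


def build_scale_space(image: GreyImage, octaves: int | None = None,
                      n_intervals: int = 3, sigma0: float = 1.6,
                      init_blur: float = 0.5) -> ScaleSpace:
    """Build the Gaussian and DoG pyramids.

    Layer i of each octave carries relative scale sigma0·2^(i/s),
    produced by incremental blurring; DoG layer i = gaussian[i+1] −
    gaussian[i].
    """
    h, w = image.shape
    if octaves is None:
        octaves = default_octaves((h, w))
    if min(h, w) / 2 ** (octaves - 1) < 8:
        raise ValueError(f"image {h}x{w} too small for {octaves} octaves")

    s = n_intervals
    rel_sigmas = [sigma0 * 2.0 ** (i / s) for i in range(s + 3)]
    gaussians: list[list[np.ndarray]] = []
    dogs: list[list[np.ndarray]] = []
    base = image.pixels.astype(np.float64)
    for o in range(octaves):
        layers = []
        if o == 0:
            first = gaussian_blur(base, math.sqrt(max(sigma0**2 - init_blur**2, 0.0)))
        else:
            # decimate the previous octave's layer at relative scale 2*sigma0
            first = gaussians[o - 1][s][::2, ::2].copy()
        layers.append(first)
        for i in range(1, s + 3):
            inc = math.sqrt(rel_sigmas[i] ** 2 - rel_sigmas[i - 1] ** 2)
            layers.append(gaussian_blur(layers[-1], inc))
        gaussians.append(layers)
        dogs.append([layers[i + 1] - layers[i] for i in range(s + 2)])
    return ScaleSpace(gaussians, dogs, sigma0, s)


def detect_extrema(space: ScaleSpace, border: int = 5) -> list[Keypoint]:
    """Lattice points strictly above or below all 26 DoG neighbours.

    A candidate in DoG layer i (1 ≤ i ≤ s) of some octave is compared
    with its 8 neighbours in the same layer and the 9 in each adjacent
    layer; points within ``border`` pixels of the layer edge are
    skipped.
    """
    kps: list[Keypoint] = []
    b = max(border, 1)
    for o, dog in enumerate(space.dogs):
        h, w = dog[0].shape
        if h <= 2 * b or w <= 2 * b:
            continue
        for i in range(1, space.n_intervals + 1):
            centre = dog[i][b:h - b, b:w - b]
            others_max = np.full(centre.shape, -np.inf)
            others_min = np.full(centre.shape, np.inf)
            for layer in (dog[i - 1], dog[i], dog[i + 1]):
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if layer is dog[i] and dr == 0 and dc == 0:
                            continue
                        shifted = layer[b + dr:h - b + dr, b + dc:w - b + dc]
                        np.maximum(others_max, shifted, out=others_max)
                        np.minimum(others_min, shifted, out=others_min)
            hits = (centre > others_max) | (centre < others_min)
            for r, c in zip(*np.nonzero(hits)):
                rr, cc = int(r) + b, int(c) + b
                kps.append(Keypoint(
                    row=rr * 2.0**o, col=cc * 2.0**o,
                    sigma=space.sigma_abs(o, i), octave=o, interval=float(i),
                    r_oct=float(rr), c_oct=float(cc),
                    response=float(dog[i][rr, cc])))
    return kps


def _dog_derivatives(dog: list[np.ndarray], i: int, r: int, c: int):
    """Central-difference gradient and Hessian of DoG at a lattice point.

    Variable order is (row, col, scale), unit spacing on all axes.
    """
    d0, d1, d2 = dog[i - 1], dog[i], dog[i + 1]
    g = 0.5 * np.array([
        d1[r + 1, c] - d1[r - 1, c],
        d1[r, c + 1] - d1[r, c - 1],
        d2[r, c] - d0[r, c],
    ])
    v = d1[r, c]
    drr = d1[r + 1, c] + d1[r - 1, c] - 2 * v
    dcc = d1[r, c + 1] + d1[r, c - 1] - 2 * v
    dss = d2[r, c] + d0[r, c] - 2 * v
    drc = 0.25 * (d1[r + 1, c + 1] - d1[r + 1, c - 1]
                  - d1[r - 1, c + 1] + d1[r - 1, c - 1])
    drs = 0.25 * (d2[r + 1, c] - d2[r - 1, c] - d0[r + 1, c] + d0[r - 1, c])
    dcs = 0.25 * (d2[r, c + 1] - d2[r, c - 1] - d0[r, c + 1] + d0[r, c - 1])
    H = np.array([[drr, drc, drs], [drc, dcc, dcs], [drs, dcs, dss]])
    return g, H


def refine_keypoint(space: ScaleSpace, kp: Keypoint, contrast_T: float = 0.04,
                    n_intervals: int | None = None, edge_r: float = 10.0,
                    max_iter: int = 5) -> Keypoint | None:
    """Subpixel refinement with contrast and edge culling.

    Fits a 3-variable quadratic to the DoG about the lattice point and
    solves for the offset; an offset component above 0.5 shifts to the
    adjacent lattice point and refits, up to ``max_iter`` times. The
    point is rejected (None) when unconverged, out of bounds, of low
    contrast (|D̂| < contrast_T/n_intervals), on an edge
    (trace²/det ≥ (edge_r+1)²/edge_r for the 2×2 spatial Hessian), or
    when the Hessian is singular.
    """
    if n_intervals is None:
        n_intervals = space.n_intervals
    dog = space.dogs[kp.octave]
    h, w = dog[0].shape
    i, r, c = int(round(kp.interval)), int(round(kp.r_oct)), int(round(kp.c_oct))
    x = np.zeros(3)
    g = np.zeros(3)
    converged = False
    for _ in range(max_iter):
        if not (1 <= i <= space.n_intervals and 1 <= r < h - 1 and 1 <= c < w - 1):
            return None
        g, H = _dog_derivatives(dog, i, r, c)
        try:
            x = np.linalg.solve(H, -g)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(x)):
            return None
        if np.all(np.abs(x) <= 0.5):
            converged = True
            break
        r += int(round(float(np.clip(x[0], -1, 1))))
        c += int(round(float(np.clip(x[1], -1, 1))))
        i += int(round(float(np.clip(x[2], -1, 1))))
    if not converged:
        return None
    d_hat = float(dog[i][r, c] + 0.5 * float(g @ x))
    if abs(d_hat) < contrast_T / n_intervals:
        return None
    v = dog[i][r, c]
    drr = dog[i][r + 1, c] + dog[i][r - 1, c] - 2 * v
    dcc = dog[i][r, c + 1] + dog[i][r, c - 1] - 2 * v
    drc = 0.25 * (dog[i][r + 1, c + 1] - dog[i][r + 1, c - 1]
                  - dog[i][r - 1, c + 1] + dog[i][r - 1, c - 1])
    tr, det = drr + dcc, drr * dcc - drc * drc
    if det <= 0 or tr * tr / det >= (edge_r + 1) ** 2 / edge_r:
        return None
    r_oct, c_oct = r + float(x[0]), c + float(x[1])
    scale = 2.0**kp.octave
    return Keypoint(
        row=r_oct * scale, col=c_oct * scale,
        sigma=space.sigma_abs(kp.octave, i + float(x[2])),
        octave=kp.octave, interval=i + float(x[2]),
        r_oct=r_oct, c_oct=c_oct, response=d_hat,
        orientation=kp.orientation)


def _gradient_layer(space: ScaleSpace, kp: Keypoint) -> tuple[np.ndarray, float]:
    """The Gaussian layer closest in scale to the keypoint, and the
    keypoint's octave-relative scale."""
    o = kp.octave
    s = space.n_intervals
    layers = space.gaussians[o]
    j = min(range(len(layers)), key=lambda i: abs(space.sigma_abs(o, i) - kp.sigma))
    return layers[j], kp.sigma / 2.0**o


def orientation_histogram(space: ScaleSpace, kp: Keypoint,
                          n_bins: int = 36, sigma_factor: float = 1.5,
                          radius_factor: float = 3.0) -> np.ndarray:
    """Gradient-orientation histogram (10° bins by default) around a
    keypoint, each sample weighted by magnitude × a Gaussian of sd
    1.5 × the keypoint scale, over a disc of 3× that sd."""
    layer, sig_rel = _gradient_layer(space, kp)
    h, w = layer.shape
    weight_sd = sigma_factor * sig_rel
    radius = max(int(round(radius_factor * weight_sd)), 1)
    r0, c0 = kp.r_oct, kp.c_oct
    rc, cc = int(round(r0)), int(round(c0))
    rlo, rhi = max(rc - radius, 1), min(rc + radius, h - 2)
    clo, chi = max(cc - radius, 1), min(cc + radius, w - 2)
    hist = np.zeros(n_bins)
    if rlo > rhi or clo > chi:
        return hist
    rr, cc_grid = np.mgrid[rlo:rhi + 1, clo:chi + 1]
    d_row = layer[rlo + 1:rhi + 2, clo:chi + 1] - layer[rlo - 1:rhi, clo:chi + 1]
    d_col = layer[rlo:rhi + 1, clo + 1:chi + 2] - layer[rlo:rhi + 1, clo - 1:chi]
    mag = np.hypot(d_row, d_col)
    ang = np.mod(np.arctan2(-d_row, d_col), TWO_PI)  # y axis up the image
    dist2 = (rr - r0) ** 2 + (cc_grid - c0) ** 2
    inside = dist2 <= radius**2
    wgt = np.exp(-dist2 / (2.0 * weight_sd**2)) * mag * inside
    bins = np.minimum((ang / (TWO_PI / n_bins)).astype(int), n_bins - 1)
    np.add.at(hist, bins.ravel(), wgt.ravel())
    return hist


def assign_orientations(space: ScaleSpace, kp: Keypoint,
                        n_bins: int = 36, peak_ratio: float = 0.8,
                        sigma_factor: float = 1.5,
                        radius_factor: float = 3.0) -> list[Keypoint]:
    """Main orientation from the histogram peak, plus at most one
    auxiliary orientation at a secondary local peak ≥ ``peak_ratio`` of
    the main one (emitted as a second keypoint with the same position
    and scale). Returns [] when the neighbourhood has no gradient."""
    hist = orientation_histogram(space, kp, n_bins, sigma_factor, radius_factor)
    peak = float(hist.max())
    if peak <= 0.0:
        return []
    binwidth = TWO_PI / n_bins
    main = int(np.argmax(hist))
    out = [replace(kp, orientation=(main + 0.5) * binwidth)]
    aux_val = -1.0
    aux_bin = -1
    for b in range(n_bins):
        if b == main:
            continue
        left, right = hist[(b - 1) % n_bins], hist[(b + 1) % n_bins]
        if hist[b] > left and hist[b] > right and hist[b] >= peak_ratio * peak:
            if hist[b] > aux_val:
                aux_val, aux_bin = float(hist[b]), b
    if aux_bin >= 0:
        out.append(replace(kp, orientation=(aux_bin + 0.5) * binwidth))
    return out


def compute_descriptor(space: ScaleSpace, kp: Keypoint,
                       grid: int = 4, n_bins: int = 8,
                       scale_factor: float = 3.0,
                       clip: float = 0.2) -> np.ndarray:
    """128-component descriptor: a ``grid×grid`` array of ``n_bins``-bin
    gradient histograms in the coordinate frame rotated to the main
    orientation, with trilinear interpolation and Gaussian weighting of
    sd = half the descriptor window width; normalised to unit length,
    clipped at ``clip``, renormalised. Samples outside the image are
    dropped."""
    if kp.orientation is None:
        raise ValueError("keypoint has no orientation")
    layer, sig_rel = _gradient_layer(space, kp)
    h, w = layer.shape
    hist_width = scale_factor * sig_rel
    radius = int(round(hist_width * math.sqrt(2) * (grid + 1) * 0.5))
    radius = min(radius, int(math.hypot(h, w)))
    r0, c0 = kp.r_oct, kp.c_oct
    rc, cc = int(round(r0)), int(round(c0))
    rlo, rhi = max(rc - radius, 1), min(rc + radius, h - 2)
    clo, chi = max(cc - radius, 1), min(cc + radius, w - 2)
    hist = np.zeros((grid + 2, grid + 2, n_bins))
    if rlo <= rhi and clo <= chi:
        rr, cg = np.mgrid[rlo:rhi + 1, clo:chi + 1]
        d_row = layer[rlo + 1:rhi + 2, clo:chi + 1] - layer[rlo - 1:rhi, clo:chi + 1]
        d_col = layer[rlo:rhi + 1, clo + 1:chi + 2] - layer[rlo:rhi + 1, clo - 1:chi]
        mag = np.hypot(d_row, d_col).ravel()
        ang = np.mod(np.arctan2(-d_row, d_col), TWO_PI).ravel()
        x = (cg - c0).ravel()          # +x along columns
        y_up = -(rr - r0).ravel()      # +y up the image
        cos_t, sin_t = math.cos(kp.orientation), math.sin(kp.orientation)
        x_rot = x * cos_t + y_up * sin_t
        y_rot = -x * sin_t + y_up * cos_t
        cbin = x_rot / hist_width + grid / 2 - 0.5
        rbin = -y_rot / hist_width + grid / 2 - 0.5
        keep = (rbin > -1) & (rbin < grid) & (cbin > -1) & (cbin < grid)
        window_sd = 0.5 * grid * hist_width
        wgt = np.exp(-(x_rot**2 + y_rot**2) / (2.0 * window_sd**2)) * mag
        obin = np.mod(ang - kp.orientation, TWO_PI) / (TWO_PI / n_bins)
        rbin, cbin, obin, wgt = rbin[keep], cbin[keep], obin[keep], wgt[keep]
        rf, cf, of = np.floor(rbin), np.floor(cbin), np.floor(obin)
        dr, dc, do = rbin - rf, cbin - cf, obin - of
        rf = rf.astype(int)
        cf = cf.astype(int)
        of = of.astype(int)
        for ir in (0, 1):
            for ic in (0, 1):
                for io in (0, 1):
                    wtri = wgt \
                        * (dr if ir else 1 - dr) \
                        * (dc if ic else 1 - dc) \
                        * (do if io else 1 - do)
                    np.add.at(hist,
                              (rf + ir + 1, cf + ic + 1, (of + io) % n_bins),
                              wtri)
    vec = hist[1:-1, 1:-1, :].ravel()
    norm = np.linalg.norm(vec)
    if norm > 0:
        vec = vec / norm
        vec = np.minimum(vec, clip)
        norm = np.linalg.norm(vec)
        if norm > 0:
            vec = vec / norm
    return vec


def detect_and_describe(image: GreyImage, cfg: SiftConfig = SiftConfig()
                        ) -> tuple[list[Keypoint], np.ndarray]:
    """Full keypoint pipeline: scale space → extrema → refinement →
    orientation(s) → descriptors. Returns the oriented keypoints and
    the (N, 128) descriptor matrix in matching order."""
    space = build_scale_space(image, cfg.octaves, cfg.n_intervals,
                              cfg.sigma0, cfg.init_blur)
    candidates = detect_extrema(space, cfg.border)
    kps: list[Keypoint] = []
    descs: list[np.ndarray] = []
    for kp in candidates:
        refined = refine_keypoint(space, kp, cfg.contrast_T, cfg.n_intervals,
                                  cfg.edge_r, cfg.max_refine_iter)
        if refined is None:
            continue
        for okp in assign_orientations(space, refined, cfg.n_orient_bins,
                                       cfg.peak_ratio, cfg.orient_sigma_factor,
                                       cfg.orient_radius_factor):
            vec = compute_descriptor(space, okp, cfg.descr_grid,
                                     cfg.descr_bins, cfg.descr_scale_factor,
                                     cfg.descr_clip)
            if vec.any():
                kps.append(okp)
                descs.append(vec)
    if descs:
        return kps, np.vstack(descs)
    return kps, np.zeros((0, cfg.descr_grid**2 * cfg.descr_bins))
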