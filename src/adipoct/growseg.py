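"""Automatic-seed region growing for the subcutaneous fat ring.

Seed points are found by casting eight rays — from the four edge
midpoints and four corners, all converging on the image centre — and
stepping a few pixels past the first body pixel each ray meets, which
lands the seed inside the subcutaneous ring without manual
interaction. Growth is breadth-first over 4-neighbourhoods under a
scale-free grey-ratio similarity criterion ``min(v, m)/max(v, m) >= τ``
against the running mean ``m`` of the accepted seed sequence, which
drifts toward the average grey value of the subcutaneous tissue as the
region grows.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, replace

import numpy as np

from adipoct.core import BACKGROUND_TOL, GreyImage, RegionMask
from adipoct.preprocess import remove_bed

log = logging.getLogger(__name__)

# ray order: N, NE, E, SE, S, SW, W, NW (start point, toward centre)
_RAY_ORDER = ["N", "NE", "E", "SE", "S", "SW", "W", "NW"]


class NoSeedError(RuntimeError):
    """No ray met tissue; caller may fall back to a manual seed."""


@dataclass(frozen=True)
class GrowConfig:
    """Tunables of seed selection and growth.

    ratio_tol
        Similarity threshold τ in (0, 1); a neighbour of grey value v
        joins the region iff ``min(v, m)/max(v, m) >= τ``.
    step_units
        Pixels to advance along the ray past the first body pixel, so
        the seed clears the skin band into the fat ring.
    entry_run
        Consecutive non-background ray samples required before the ray
        is considered to have entered the body (rejects isolated noise
        specks in the air).
    mean_mode
        "sequence": m is the running mean of accepted pixels (default);
        "frozen": m stays at the initial seed mean; "image": m is the
        mean of all non-background pixels.
    """

    ratio_tol: float = 0.9
    step_units: int = 3
    entry_run: int = 5
    background_tol: float = BACKGROUND_TOL
    mean_mode: str = "sequence"

    def __post_init__(self) -> None:
        if not 0.0 < self.ratio_tol < 1.0:
            raise ValueError("ratio_tol must lie in (0, 1)")
        if self.step_units < 1:
            raise ValueError("step_units must be >= 1")
        if self.mean_mode not in ("sequence", "frozen", "image"):
            raise ValueError(f"unknown mean_mode {self.mean_mode!r}")


def _ray_starts(h: int, w: int) -> list[tuple[str, np.ndarray]]:
    top, bot = 0.0, float(h - 1)
    left, right = 0.0, float(w - 1)
    midr, midc = (h - 1) / 2.0, (w - 1) / 2.0
    return [
        ("N", np.array([top, midc])),
        ("NE", np.array([top, right])),
        ("E", np.array([midr, right])),
        ("SE", np.array([bot, right])),
        ("S", np.array([bot, midc])),
        ("SW", np.array([bot, left])),
        ("W", np.array([midr, left])),
        ("NW", np.array([top, left])),
    ]


def select_seeds(image: GreyImage, cfg: GrowConfig = GrowConfig()
                 ) -> list[tuple[int, int]]:
    """Place one seed per ray; deterministic N, NE, ..., NW order.

    Each ray marches from its border start toward the image centre in
    half-pixel steps; on meeting ``entry_run`` consecutive
    non-background samples it declares body entry at the first of them,
    advances ``step_units`` pixels of arc length further, and records
    that pixel. Rays that never meet tissue contribute nothing;
    duplicates are dropped. Raises :class:`NoSeedError` if no seed is
    found.
    """
    h, w = image.shape
    centre = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    pix = image.pixels
    seeds: list[tuple[int, int]] = []
    for name, start in _ray_starts(h, w):
        direction = centre - start
        length = float(np.hypot(*direction))
        if length == 0:
            continue
        unit = direction / length
        entry_t: float | None = None
        run_start: float | None = None
        run: list[tuple[int, int]] = []
        t = 0.0
        while t <= length:
            p = start + t * unit
            r, c = int(round(p[0])), int(round(p[1]))
            if not run or (r, c) != run[-1]:
                if pix[r, c] > cfg.background_tol:
                    if not run:
                        run_start = t
                    run.append((r, c))
                    if len(run) >= cfg.entry_run:
                        entry_t = run_start
                        break
                else:
                    run = []
                    run_start = None
            t += 0.5
        if entry_t is None:
            continue
        sp = start + (entry_t + cfg.step_units) * unit
        seed = (int(round(sp[0])), int(round(sp[1])))
        if 0 <= seed[0] < h and 0 <= seed[1] < w and seed not in seeds:
            seeds.append(seed)
    if not seeds:
        raise NoSeedError("no ray met tissue; supply a manual seed")
    return seeds


def grow_region(image: GreyImage, seeds: list[tuple[int, int]],
                cfg: GrowConfig = GrowConfig()) -> RegionMask:
    """Breadth-first growth from ``seeds`` under the grey-ratio criterion.

    The frontier is FIFO, neighbours are tested in fixed N, S, W, E
    order, and each accepted pixel updates the running mean
    incrementally, so the (order-dependent) result is fully
    deterministic.
    """
    if not seeds:
        raise ValueError("empty seed list")
    h, w = image.shape
    pix = image.pixels
    for r, c in seeds:
        if pix[r, c] <= cfg.background_tol:
            raise ValueError(f"seed ({r},{c}) is a background pixel")

    visited = np.zeros((h, w), dtype=bool)
    accepted = np.zeros((h, w), dtype=bool)
    total = 0.0
    count = 0
    frontier: deque[tuple[int, int]] = deque()
    for r, c in seeds:
        if not visited[r, c]:
            visited[r, c] = True
            accepted[r, c] = True
            total += pix[r, c]
            count += 1
            frontier.append((r, c))

    if cfg.mean_mode == "image":
        fg = image.foreground(cfg.background_tol)
        frozen_mean = float(pix[fg].mean())
    elif cfg.mean_mode == "frozen":
        frozen_mean = total / count
    else:
        frozen_mean = None

    while frontier:
        r, c = frontier.popleft()
        m = frozen_mean if frozen_mean is not None else total / count
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):  # N, S, W, E
            nr, nc = r + dr, c + dc
            if not (0 <= nr < h and 0 <= nc < w) or visited[nr, nc]:
                continue
            v = pix[nr, nc]
            if v <= cfg.background_tol:
                continue
            visited[nr, nc] = True
            lo, hi = (v, m) if v < m else (m, v)
            if hi > 0 and lo / hi >= cfg.ratio_tol:
                accepted[nr, nc] = True
                total += v
                count += 1
                frontier.append((nr, nc))
    return RegionMask(accepted, "subcutaneous_fat")


def segment_subcutaneous(image: GreyImage, cfg: GrowConfig = GrowConfig(),
                         manual_seed: tuple[int, int] | None = None,
                         bed_removed: bool = False) -> RegionMask:
    """Full chain: bed removal, seed selection, region growth.

    ``manual_seed`` replaces automatic selection (the semiautomatic
    fallback). Automatic seeds are screened before growth: seeds on
    background (a ray that overshot a thin ring) are dropped, and so
    are seeds whose grey value fails the similarity criterion against
    the median seed value — all valid seeds sample the same
    subcutaneous tissue, so a discordant one marks a failed ray (e.g. a
    noise speck in the air), and keeping it would corrupt the running
    mean that drives growth.
    """
    if not bed_removed:
        image, _ = remove_bed(image, background_tol=cfg.background_tol)
    if manual_seed is not None:
        seeds = [manual_seed]
    else:
        seeds = select_seeds(image, cfg)
        kept = [s for s in seeds if image.pixels[s] > cfg.background_tol]
        if len(kept) < len(seeds):
            log.warning("dropped %d seed(s) on background", len(seeds) - len(kept))
        if not kept:
            raise NoSeedError("all automatic seeds landed on background")
        med = float(np.median([image.pixels[s] for s in kept]))
        consistent = []
        for s in kept:
            v = image.pixels[s]
            lo, hi = (v, med) if v < med else (med, v)
            if hi > 0 and lo / hi >= cfg.ratio_tol:
                consistent.append(s)
            else:
                log.warning("dropped discordant seed %s (v=%.3f, median=%.3f)",
                            s, v, med)
        if not consistent:
            raise NoSeedError("no two seeds agree on a tissue grey level")
        seeds = consistent
    mask = grow_region(image, seeds, cfg)
    log.info("region growing: %d seeds, %d pixels, final mean %.4f",
             len(seeds), mask.count, float(image.pixels[mask.bits].mean()))
    return mask
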