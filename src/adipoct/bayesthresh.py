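"""Iterative Bayes threshold selection and global segmentation.

A two-class Gaussian Bayes rule with equal variances assigns a pixel to
the class with the higher posterior; its decision boundary is the
midpoint of the two class means. Starting from the midpoint of the
minimum and maximum grey levels, the threshold is repeatedly reset to
the midpoint of the below/above class means until successive values
differ by less than ``eps`` — the classical iterative-mean (ISODATA)
scheme. Background (air) pixels are excluded from the histogram so they
do not drag the lower class mean toward zero.

The class priors implied by the class counts are computed and logged at
each step; under the equal-variance assumption they do not move the
boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from adipoct.core import BACKGROUND_TOL, DegenerateInputError, GreyImage, RegionMask

log = logging.getLogger(__name__)


@dataclass
class ThresholdTrace:
    """Threshold sequence and per-iteration class means."""

    thresholds: list[float]
    mean_below: list[float]
    mean_above: list[float]
    prior_below: list[float]
    eps: float
    converged: bool

    @property
    def threshold(self) -> float:
        """The final (optimal) threshold."""
        return self.thresholds[-1]

    def to_rows(self) -> list[dict]:
        return [
            {"iteration": i, "t": t, "mu_below": mb, "mu_above": ma,
             "prior_below": pb}
            for i, (t, mb, ma, pb) in enumerate(
                zip(self.thresholds, self.mean_below, self.mean_above,
                    self.prior_below))
        ]


def iterate_threshold(image: GreyImage, eps: float = 1e-4, max_iter: int = 100,
                      background_tol: float = BACKGROUND_TOL) -> ThresholdTrace:
    """Find the iterative-mean threshold of the non-background histogram.

    Starts at ``t0 = (min + max)/2``; each step partitions pixels at t,
    takes the below/above class means, and moves t to their midpoint;
    stops when ``|Δt| < eps`` or after ``max_iter`` steps.

    Raises :class:`DegenerateInputError` on a (near-)constant image.
    """
    values = image.pixels[image.foreground(background_tol)]
    if values.size == 0:
        raise DegenerateInputError("no non-background pixels")
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        raise DegenerateInputError("constant image: no threshold exists")

    t = (vmin + vmax) / 2.0
    thresholds = [t]
    mean_below: list[float] = []
    mean_above: list[float] = []
    prior_below: list[float] = []
    converged = False
    for _ in range(max_iter):
        below = values[values <= t]
        above = values[values > t]
        if above.size == 0:  # t == vmax: everything below
            mb, ma = float(below.mean()), vmax
        else:
            mb, ma = float(below.mean()), float(above.mean())
        pb = below.size / values.size
        mean_below.append(mb)
        mean_above.append(ma)
        prior_below.append(pb)
        t_next = (mb + ma) / 2.0
        thresholds.append(t_next)
        log.debug("threshold iter %d: t=%.6f mu_b=%.6f mu_a=%.6f prior_b=%.3f",
                  len(thresholds) - 1, t_next, mb, ma, pb)
        if abs(t_next - t) < eps:
            converged = True
            t = t_next
            break
        t = t_next
    return ThresholdTrace(thresholds, mean_below, mean_above, prior_below,
                          eps=eps, converged=converged)


def segment_by_threshold(image: GreyImage, t: float,
                         background_tol: float = BACKGROUND_TOL
                         ) -> tuple[RegionMask, RegionMask]:
    """Split non-background pixels into (below, above) masks at ``t``."""
    if not 0.0 <= t <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    fg = image.foreground(background_tol)
    below = fg & (image.pixels <= t)
    above = fg & (image.pixels > t)
    return RegionMask(below, "below_threshold"), RegionMask(above, "above_threshold")
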