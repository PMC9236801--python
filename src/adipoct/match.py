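"""Descriptor matching and the registration experiments.

Matching uses Lowe's nearest/second-nearest ratio test on Euclidean
descriptor distance. The experiment drivers mirror the two study
designs: registering a part (crop) against the whole slice, and
matching slices within and between groups (a group = one subject) to
rank database images by match count.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np

from adipoct.core import GreyImage
from adipoct.sift import Keypoint, SiftConfig, detect_and_describe

log = logging.getLogger(__name__)


@dataclass
class MatchSet:
    """Accepted descriptor pairings, sorted by ascending distance."""

    pairs: list[tuple[int, int, float]]
    n_keypoints_a: int
    n_keypoints_b: int
    ratio_used: float

    @property
    def n_matches(self) -> int:
        return len(self.pairs)


@dataclass
class ReportRow:
    """One experiment pairing, mirroring the Key points/Matches/Time
    reporting columns."""

    group_a: str
    group_b: str
    n_keypoints_a: int
    n_keypoints_b: int
    n_matches: int
    elapsed_seconds: float
    kind: str = ""  # "intra" / "inter" / "pair"


def _two_smallest(d: np.ndarray) -> tuple[int, float, float]:
    """Index of the smallest entry plus the two smallest values."""
    j1 = int(np.argmin(d))
    d1 = float(d[j1])
    rest = np.delete(d, j1)
    d2 = float(rest.min()) if rest.size else np.inf
    return j1, d1, d2


def match_descriptors(desc_a: np.ndarray, desc_b: np.ndarray,
                      ratio: float = 0.8, use_tree: bool = False,
                      single_cutoff: float = 0.3) -> MatchSet:
    """Ratio-test matching from A's side.

    For each descriptor in A the nearest and second-nearest neighbours
    in B are found by Euclidean distance; the pair is accepted iff
    ``d1/d2 < ratio`` (ties d1 = d2 are rejected). With fewer than two
    descriptors in B the ratio test is undefined; the single neighbour
    is accepted iff ``d1 < single_cutoff`` (logged). ``use_tree``
    switches to a k-d tree search that returns identical results to the
    exhaustive scan.
    """
    a = np.asarray(desc_a, dtype=np.float64)
    b = np.asarray(desc_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("descriptor lists must be non-empty")
    pairs: list[tuple[int, int, float]] = []
    if b.shape[0] < 2:
        log.warning("only %d descriptor(s) in B: ratio test undefined, "
                    "using absolute cutoff %.3f", b.shape[0], single_cutoff)
        for i in range(a.shape[0]):
            d1 = float(np.linalg.norm(a[i] - b[0]))
            if d1 < single_cutoff:
                pairs.append((i, 0, d1))
    elif use_tree:
        from sklearn.neighbors import KDTree

        tree = KDTree(b)
        dist, idx = tree.query(a, k=2)
        for i in range(a.shape[0]):
            d1, d2 = float(dist[i, 0]), float(dist[i, 1])
            if d2 > 0 and d1 / d2 < ratio:
                pairs.append((i, int(idx[i, 0]), d1))
    else:
        for i in range(a.shape[0]):
            d = np.linalg.norm(b - a[i], axis=1)
            j1, d1, d2 = _two_smallest(d)
            if d2 > 0 and d1 / d2 < ratio:
                pairs.append((i, j1, d1))
    pairs.sort(key=lambda p: (p[2], p[0]))
    return MatchSet(pairs, a.shape[0], b.shape[0], ratio)


def match_images(img_a: GreyImage, img_b: GreyImage,
                 cfg: SiftConfig = SiftConfig(), ratio: float = 0.8,
                 name_a: str = "A", name_b: str = "B",
                 ) -> tuple[MatchSet, ReportRow,
                            list[Keypoint], list[Keypoint]]:
    """Run the keypoint pipeline on both images and match descriptors.

    Returns the match set, a report row (counts and wall time), and the
    two keypoint lists so matches can be mapped back to coordinates.
    """
    t0 = time.perf_counter()
    kps_a, desc_a = detect_and_describe(img_a, cfg)
    kps_b, desc_b = detect_and_describe(img_b, cfg)
    if len(kps_a) == 0 or len(kps_b) == 0:
        log.warning("zero keypoints (A=%d, B=%d): no matches",
                    len(kps_a), len(kps_b))
        ms = MatchSet([], len(kps_a), len(kps_b), ratio)
    else:
        ms = match_descriptors(desc_a, desc_b, ratio=ratio)
    elapsed = time.perf_counter() - t0
    row = ReportRow(name_a, name_b, len(kps_a), len(kps_b),
                    ms.n_matches, elapsed, kind="pair")
    return ms, row, kps_a, kps_b


def mutual_best(ab: MatchSet, ba: MatchSet) -> set[tuple[int, int]]:
    """Pairs accepted in both directions (A→B and B→A)."""
    fwd = {(i, j) for i, j, _ in ab.pairs}
    rev = {(i, j) for j, i, _ in ba.pairs}
    return fwd & rev


def group_experiment(groups: dict[str, list[GreyImage]],
                     cfg: SiftConfig = SiftConfig(), ratio: float = 0.8,
                     ) -> list[ReportRow]:
    """Match every within-group and between-group image pair.

    Rows are tagged "intra"/"inter"; summary mean rows (one per kind)
    are appended with group names "mean_intra"/"mean_inter".
    """
    names = list(groups)
    flat = [(g, i, img) for g in names for i, img in enumerate(groups[g])]
    feats = {}
    for g, i, img in flat:
        t0 = time.perf_counter()
        feats[(g, i)] = detect_and_describe(img, cfg) + (time.perf_counter() - t0,)
    rows: list[ReportRow] = []
    for ai in range(len(flat)):
        for bi in range(ai + 1, len(flat)):
            ga, ia, _ = flat[ai]
            gb, ib, _ = flat[bi]
            kps_a, desc_a, ta = feats[(ga, ia)]
            kps_b, desc_b, tb = feats[(gb, ib)]
            t0 = time.perf_counter()
            if len(kps_a) and len(kps_b):
                ms = match_descriptors(desc_a, desc_b, ratio=ratio)
                n = ms.n_matches
            else:
                n = 0
            elapsed = ta + tb + (time.perf_counter() - t0)
            rows.append(ReportRow(f"{ga}[{ia}]", f"{gb}[{ib}]",
                                  len(kps_a), len(kps_b), n, elapsed,
                                  kind="intra" if ga == gb else "inter"))
    for kind in ("intra", "inter"):
        sub = [r for r in rows if r.kind == kind]
        if sub:
            rows.append(ReportRow(
                f"mean_{kind}", f"mean_{kind}",
                int(round(np.mean([r.n_keypoints_a for r in sub]))),
                int(round(np.mean([r.n_keypoints_b for r in sub]))),
                int(round(np.mean([r.n_matches for r in sub]))),
                float(np.mean([r.elapsed_seconds for r in sub])),
                kind=f"mean_{kind}"))
    return rows


def report_to_tsv(rows: list[ReportRow], path) -> None:
    """Write report rows as TSV with the documented header."""
    import pandas as pd

    df = pd.DataFrame([{
        "group_a": r.group_a, "group_b": r.group_b,
        "keypoints_a": r.n_keypoints_a, "keypoints_b": r.n_keypoints_b,
        "matches": r.n_matches, "time_s": round(r.elapsed_seconds, 4),
        "kind": r.kind,
    } for r in rows])
    df.to_csv(path, sep="\t", index=False)
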