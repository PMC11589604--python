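"""Loop-closure drift correction.

Chained pairwise registration accumulates error.  Spatially adjacent — not
temporally sequential — frame pairs are re-registered directly; the mismatch
between a frame's chained pose and its directly measured pose is the loop
residual.  Each residual is distributed over the intervening chain by
parameter-wise linear interpolation (translation, rotation angle, log-scale),
later frames receiving larger fractions, and frames beyond the closure
receiving the full correction so the chain stays consistent.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from . import transforms as tf
from .config import FeatureConfig
from .features import EstimationError, detect_features, match_features, estimate_affine
from .mapper import BladderMap, Frame, render_map

__all__ = [
    "LoopClosure",
    "find_spatial_neighbors",
    "measure_loop_residual",
    "measure_loop_residuals",
    "apply_drift_correction",
]


@dataclass
class LoopClosure:
    """A direct registration between two temporally distant frames.

    ``residual`` is the canvas-frame correction ``(pose_a . direct_ab) .
    pose_b^-1``: identity when the chain agrees with the direct measurement.
    """

    index_a: int
    index_b: int
    residual: np.ndarray  # 2x3, measured against the poses at measure time
    inlier_count: int = 0
    direct: np.ndarray | None = None  # 2x3 direct b -> a registration

    def __post_init__(self) -> None:
        self.residual = np.asarray(self.residual, dtype=float).reshape(2, 3)
        if not np.all(np.isfinite(self.residual)):
            raise ValueError("non-finite residual")
        if self.direct is not None:
            self.direct = np.asarray(self.direct, dtype=float).reshape(2, 3)


def _footprints(bmap: BladderMap):
    corners = tf.frame_corners(bmap.frame_shape)
    return [tf.apply_transform(p.matrix, corners) for p in bmap.poses]


def find_spatial_neighbors(
    bmap: BladderMap,
    min_gap: int = 10,
    max_center_dist: float | None = None,
    min_overlap: float = 0.25,
) -> list[tuple[int, int]]:
    """Candidate loop-closure pairs: frames at least ``min_gap`` apart in time
    whose projected centers are close and whose footprints overlap.

    At most one pair is retained per later frame (the largest overlap), so
    corrections stay independent.  Returned as (index_a, index_b) with
    a < b, sorted by b.
    """
    if bmap.frame_shape is None:
        raise ValueError("map has no frame shape")
    h, w = bmap.frame_shape
    if max_center_dist is None:
        max_center_dist = 1.5 * float(np.hypot(h, w))
    feet = _footprints(bmap)
    centers = np.array([f.mean(axis=0) for f in feet])
    polys = [Polygon(f) for f in feet]
    areas = [p.area for p in polys]
    n = len(bmap.poses)
    order = [p.frame_index for p in bmap.poses]
    best: dict[int, tuple[float, int]] = {}
    for jb in range(n):
        for ja in range(jb):
            if abs(order[jb] - order[ja]) < max(min_gap, 2):
                continue
            if np.linalg.norm(centers[jb] - centers[ja]) > max_center_dist:
                continue
            inter = polys[ja].intersection(polys[jb]).area
            overlap = inter / max(min(areas[ja], areas[jb]), 1e-9)
            if overlap < min_overlap:
                continue
            if jb not in best or overlap > best[jb][0]:
                best[jb] = (overlap, ja)
    return sorted((order[ja], order[jb]) for jb, (_, ja) in best.items())


def measure_loop_residual(
    pair: tuple[int, int],
    frames: list[Frame],
    bmap: BladderMap,
    feature_config: FeatureConfig | None = None,
) -> LoopClosure:
    """Register frame b directly against frame a and express the mismatch of
    b's chained pose as a canvas-frame residual transform.

    Raises :class:`~cystomap.features.EstimationError` when matching fails;
    callers skip such pairs.
    """
    config = feature_config or FeatureConfig()
    ia, ib = pair
    by_index = {f.index: f for f in frames}
    fa, fb = by_index[ia], by_index[ib]
    feats_a = detect_features(fa.pixels, fa.mask, config, ia)
    feats_b = detect_features(fb.pixels, fb.mask, config, ib)
    matches = match_features(feats_b, feats_a, config)
    direct = estimate_affine(matches, feats_b, feats_a, config)  # b -> a
    pose_a = bmap.pose_of(ia).matrix
    pose_b = bmap.pose_of(ib).matrix
    measured_b = tf.compose(pose_a, direct.matrix)
    residual = tf.compose(measured_b, tf.invert(pose_b))
    return LoopClosure(ia, ib, residual, direct.inlier_count, direct=direct.matrix)


def measure_loop_residuals(
    pairs: list[tuple[int, int]],
    frames: list[Frame],
    bmap: BladderMap,
    feature_config: FeatureConfig | None = None,
) -> list[LoopClosure]:
    """Measure residuals for all candidate pairs, skipping failures."""
    closures = []
    for pair in pairs:
        try:
            closures.append(measure_loop_residual(pair, frames, bmap, feature_config))
        except EstimationError:
            continue
    return closures


def apply_drift_correction(
    bmap: BladderMap,
    closures: list[LoopClosure],
    frames: list[Frame] | None = None,
) -> BladderMap:
    """Distribute loop residuals over the pose chain and re-render.

    Closures are processed in increasing ``index_b`` order.  For a closure
    (a, b), frame j in (a, b] receives the fraction (j-a)/(b-a) of the
    residual, interpolated parameter-wise in (tx, ty, theta, log-scale);
    frames beyond b receive the full residual.  Frame a (and in particular
    frame 0) is never moved by its own closure.

    When ``frames`` is given the canvas is re-rendered from the corrected
    poses; otherwise only poses are updated.
    """
    if not closures:
        logging.getLogger(__name__).info("no loop closures; map left unchanged")
        return bmap
    t0 = time.perf_counter()
    order = {p.frame_index: k for k, p in enumerate(bmap.poses)}
    # widest spans first: global corrections land before local refinements,
    # so small late closures are not disturbed by large ones
    span = lambda c: abs(order[c.index_b] - order[c.index_a])  # noqa: E731
    for closure in sorted(closures, key=lambda c: (-span(c), c.index_b)):
        ka, kb = order[closure.index_a], order[closure.index_b]
        direct = closure.direct
        if kb < ka:  # anchor is always the earlier frame
            ka, kb = kb, ka
            direct = None if direct is None else tf.invert(direct)
        if direct is not None:
            # earlier closures have already moved the poses: refresh the
            # residual from the current chain and the (pose-independent)
            # direct registration before distributing it
            residual = tf.compose(
                tf.compose(bmap.poses[ka].matrix, direct),
                tf.invert(bmap.poses[kb].matrix),
            )
        else:
            residual = closure.residual
        txr, tyr, theta_r, scale_r = tf.similarity_params(residual)
        log_s = np.log(scale_r)
        for k in range(ka + 1, len(bmap.poses)):
            frac = min(1.0, (k - ka) / (kb - ka))
            corr = tf.similarity_from_params(
                frac * txr, frac * tyr, frac * theta_r, float(np.exp(frac * log_s))
            )
            bmap.poses[k].matrix = tf.compose(corr, bmap.poses[k].matrix)
    if frames is not None:
        render_map(bmap, frames)
    bmap.stats.drift_seconds += time.perf_counter() - t0
    return bmap
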