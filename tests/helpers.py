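"""Shared oracle helpers for the test suite.

These deliberately use brute-force/closed-form computations independent of
the library code paths they check.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import Polygon

from cystomap import transforms as tf


def hom_product(mats) -> np.ndarray:
    """Brute-force 3x3 homogeneous chain product oracle."""
    out = np.eye(3)
    for m in mats:
        m3 = np.eye(3)
        m3[:2, :] = np.asarray(m, dtype=float)
        out = out @ m3
    return out[:2, :]


def expected_canvas_pose(bmap, truth_poses, i: int) -> np.ndarray:
    """Ground-truth pose of frame i in canvas coordinates.

    The map is anchored at frame 0, so canvas coords equal frame-0 coords up
    to the map's cumulative offset.
    """
    rel = tf.compose(tf.invert(truth_poses[0]), truth_poses[i])
    return tf.compose(bmap.offset, rel)


def frame_center(shape) -> np.ndarray:
    h, w = shape
    return np.array([(w - 1) / 2.0, (h - 1) / 2.0])


def pose_errors(actual: np.ndarray, expected: np.ndarray, shape) -> tuple[float, float, float]:
    """(translation error at frame center [px], rotation error [deg],
    relative scale error)."""
    c = frame_center(shape)
    dt = float(
        np.linalg.norm(
            tf.apply_transform(actual, c) - tf.apply_transform(expected, c)
        )
    )
    _, _, th_a, s_a = tf.similarity_params(actual)
    _, _, th_e, s_e = tf.similarity_params(expected)
    dr = np.degrees(abs((th_a - th_e + np.pi) % (2 * np.pi) - np.pi))
    ds = abs(s_a / s_e - 1.0)
    return dt, float(dr), float(ds)


def footprint_overlap(pose_a, pose_b, shape) -> float:
    """Fractional overlap of two projected frame footprints (oracle uses
    shapely polygon intersection over the smaller footprint)."""
    corners = tf.frame_corners(shape)
    pa = Polygon(tf.apply_transform(pose_a, corners))
    pb = Polygon(tf.apply_transform(pose_b, corners))
    inter = pa.intersection(pb).area
    return inter / min(pa.area, pb.area)


def biased_chain(truth_poses, bias=(0.2, 0.0)) -> np.ndarray:
    """Chain ground-truth pairwise transforms with a per-step translation
    bias injected, anchored at frame 0 (closed-form accumulation oracle)."""
    out = [tf.compose(tf.invert(truth_poses[0]), truth_poses[0])]
    for i in range(1, len(truth_poses)):
        pairwise = tf.compose(tf.invert(truth_poses[i - 1]), truth_poses[i])
        biased = tf.compose(tf.translation(*bias), pairwise)
        out.append(tf.compose(out[-1], biased))
    return np.stack(out)
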