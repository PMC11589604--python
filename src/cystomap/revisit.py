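"""Relocalization of a later ("revisit") sweep inside a previously built map.

The first revisit frame is matched against features detected on the whole map
canvas (global search, no position prior).  Each subsequent frame first
attempts a direct map match restricted to the previous footprint dilated by
one frame size; when that fails, the frame is chained from the previous
localized frame (frame-to-frame transform, or the last accepted inter-frame
motion when even that fails).  Overlay semantics: red polyline for the sweep
path, green dot per localized frame, blue arrow for the in-plane rotation of
the cystoscope relative to the map's initial frame.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.draw import disk, line

from . import transforms as tf
from .config import FeatureConfig
from .features import (
    EstimationError,
    FeatureSet,
    detect_features,
    estimate_affine,
    match_features,
)
from .mapper import BladderMap, Frame

__all__ = [
    "RevisitLocalization",
    "LocalizationError",
    "build_map_features",
    "localize_first_frame",
    "track_revisit",
    "matched_fraction",
    "render_overlay",
]


class LocalizationError(RuntimeError):
    """Raised when the first revisit frame cannot be placed in the map."""

    def __init__(self, message: str, n_features: int = 0, n_matches: int = 0):
        self.n_features = n_features
        self.n_matches = n_matches
        super().__init__(message)


@dataclass
class RevisitLocalization:
    """Pose of one revisit frame in map-canvas coordinates."""

    frame_index: int
    pose: np.ndarray | None  # 2x3 revisit-frame -> canvas; None when failed
    status: str  # "matched_to_map" | "tracked_from_previous" | "failed"
    rotation_deg: float  # in-plane rotation vs the map's initial frame
    inlier_count: int = 0

    def __post_init__(self) -> None:
        if self.status not in ("matched_to_map", "tracked_from_previous", "failed"):
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == "failed":
            self.pose = None
        else:
            self.pose = np.asarray(self.pose, dtype=float).reshape(2, 3)
        if not -180.0 < self.rotation_deg <= 180.0 and np.isfinite(self.rotation_deg):
            raise ValueError("rotation_deg out of (-180, 180]")


def build_map_features(
    bmap: BladderMap, config: FeatureConfig | None = None
) -> FeatureSet:
    """Detect features once on the (possibly drift-corrected) canvas.

    Cache the result and pass it to the localization functions when
    processing many frames.
    """
    return detect_features(bmap.canvas, bmap.canvas_mask, config, frame_index=-1)


def _subset_in_box(feats: FeatureSet, x0, y0, x1, y1) -> FeatureSet:
    xy = feats.positions
    keep = (xy[:, 0] >= x0) & (xy[:, 0] <= x1) & (xy[:, 1] >= y0) & (xy[:, 1] <= y1)
    return FeatureSet(feats.frame_index, feats.keypoints[keep], feats.descriptors[keep])


def _rotation_vs_initial(bmap: BladderMap, pose: np.ndarray) -> float:
    _, _, theta0, _ = tf.similarity_params(bmap.poses[0].matrix)
    _, _, theta, _ = tf.similarity_params(pose)
    deg = np.degrees(theta - theta0)
    deg = (deg + 180.0) % 360.0 - 180.0
    return float(180.0 if deg == -180.0 else deg)


def localize_first_frame(
    bmap: BladderMap,
    frame: Frame,
    config: FeatureConfig | None = None,
    map_features: FeatureSet | None = None,
) -> RevisitLocalization:
    """Place a revisit frame in the map by a global feature search."""
    config = config or FeatureConfig()
    if not bmap.canvas_mask.any():
        raise ValueError("map canvas is empty")
    if map_features is None:
        map_features = build_map_features(bmap, config)
    feats = detect_features(frame.pixels, frame.mask, config, frame.index)
    matches = match_features(feats, map_features, config)
    try:
        ft = estimate_affine(matches, feats, map_features, config)
    except EstimationError:
        # global search with no prior: retry once with a relaxed ratio test
        # before giving up (weak-texture regions yield few strict matches)
        relaxed = replace(config, ratio=min(0.9, config.ratio + 0.1))
        matches = match_features(feats, map_features, relaxed)
        try:
            ft = estimate_affine(matches, feats, map_features, relaxed)
        except EstimationError as err:
            raise LocalizationError(
                f"first revisit frame not found in map: {err} "
                f"({len(feats)} features, {len(matches)} matches)",
                n_features=len(feats),
                n_matches=len(matches),
            ) from err
    return RevisitLocalization(
        frame_index=frame.index,
        pose=ft.matrix,
        status="matched_to_map",
        rotation_deg=_rotation_vs_initial(bmap, ft.matrix),
        inlier_count=ft.inlier_count,
    )


def track_revisit(
    bmap: BladderMap,
    frames: list[Frame],
    config: FeatureConfig | None = None,
    map_features: FeatureSet | None = None,
) -> list[RevisitLocalization]:
    """Localize every frame of a revisit sweep in the map.

    Failure of the first frame aborts the whole sequence (there is no
    reference to track from).  Later failures degrade to
    ``tracked_from_previous``.
    """
    if not frames:
        raise ValueError("empty revisit sequence")
    config = config or FeatureConfig()
    if map_features is None:
        map_features = build_map_features(bmap, config)
    first = localize_first_frame(bmap, frames[0], config, map_features)
    out = [first]
    prev_pose = first.pose
    prev_feats = detect_features(frames[0].pixels, frames[0].mask, config, frames[0].index)
    last_motion = tf.identity()  # previous frame -> current frame pose delta
    fh, fw = frames[0].shape
    for frame in frames[1:]:
        feats = detect_features(frame.pixels, frame.mask, config, frame.index)
        pose, status, inliers = None, "failed", 0
        # 1) direct map match near the previous footprint (dilated one frame)
        corners = tf.apply_transform(prev_pose, tf.frame_corners((fh, fw)))
        local = _subset_in_box(
            map_features,
            corners[:, 0].min() - fw,
            corners[:, 1].min() - fh,
            corners[:, 0].max() + fw,
            corners[:, 1].max() + fh,
        )
        try:
            matches = match_features(feats, local, config)
            ft = estimate_affine(matches, feats, local, config)
            pose, status, inliers = ft.matrix, "matched_to_map", ft.inlier_count
        except EstimationError:
            # 2) chain from the previous frame
            try:
                matches = match_features(feats, prev_feats, config)
                ft = estimate_affine(matches, feats, prev_feats, config)
                pose = tf.compose(prev_pose, ft.matrix)
                status, inliers = "tracked_from_previous", ft.inlier_count
            except EstimationError:
                # 3) inherit the last accepted inter-frame motion
                pose, status = tf.compose(prev_pose, last_motion), "tracked_from_previous"
        if status != "tracked_from_previous" or inliers > 0:
            last_motion = tf.compose(tf.invert(prev_pose), pose)
        out.append(
            RevisitLocalization(
                frame_index=frame.index,
                pose=pose,
                status=status,
                rotation_deg=_rotation_vs_initial(bmap, pose),
                inlier_count=inliers,
            )
        )
        prev_pose, prev_feats = pose, feats
    return out


def matched_fraction(localizations: list[RevisitLocalization]) -> float:
    """Exact fraction of frames with status ``matched_to_map``."""
    if not localizations:
        return 0.0
    n = sum(1 for lo in localizations if lo.status == "matched_to_map")
    return n / len(localizations)


def _draw_line(img, p0, p1, color):
    h, w = img.shape[:2]
    r0, c0 = int(round(p0[1])), int(round(p0[0]))
    r1, c1 = int(round(p1[1])), int(round(p1[0]))
    rr, cc = line(r0, c0, r1, c1)
    keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    img[rr[keep], cc[keep]] = color


def render_overlay(
    bmap: BladderMap,
    localizations: list[RevisitLocalization],
    frame_shape: tuple[int, int] | None = None,
    arrow_length: float | None = None,
) -> np.ndarray:
    """Render the revisit overlay on a copy of the map canvas.

    Red polyline through the localized frame centers (the sweep path), a
    green dot at each localized frame's center, and a blue arrow per frame
    showing the cystoscope rotation relative to the map's initial frame.
    """
    placed = [lo for lo in localizations if lo.status != "failed"]
    if not placed:
        raise ValueError("no non-failed localizations to render")
    frame_shape = frame_shape or bmap.frame_shape
    if frame_shape is None:
        raise ValueError("frame shape unknown")
    fh, fw = frame_shape
    center = np.array([(fw - 1) / 2.0, (fh - 1) / 2.0])
    canvas = bmap.canvas
    if canvas.ndim == 2:
        img = np.stack([canvas] * 3, axis=-1).astype(np.uint8)
    else:
        img = canvas.astype(np.uint8).copy()
    red, green, blue = (255, 0, 0), (0, 200, 0), (0, 80, 255)
    centers = [tf.apply_transform(lo.pose, center)[0] for lo in placed]
    for p0, p1 in zip(centers[:-1], centers[1:]):
        _draw_line(img, p0, p1, red)
    if arrow_length is None:
        arrow_length = 0.3 * min(fh, fw)
    # reference direction: the initial frame's "up" axis in canvas coords
    _, _, theta0, _ = tf.similarity_params(bmap.poses[0].matrix)
    for lo, c in zip(placed, centers):
        ang = theta0 + np.radians(lo.rotation_deg)
        direction = np.array([np.sin(ang), -np.cos(ang)])  # frame-up, rotated
        tip = c + arrow_length * direction
        _draw_line(img, c, tip, blue)
        for head_ang in (np.radians(150), np.radians(-150)):
            cos_a, sin_a = np.cos(head_ang), np.sin(head_ang)
            head_dir = np.array(
                [
                    cos_a * direction[0] - sin_a * direction[1],
                    sin_a * direction[0] + cos_a * direction[1],
                ]
            )
            _draw_line(img, tip, tip + 0.25 * arrow_length * head_dir, blue)
    h, w = img.shape[:2]
    for c in centers:
        rr, cc = disk((c[1], c[0]), radius=3, shape=(h, w))
        img[rr, cc] = green
    return img
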