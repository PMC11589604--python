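"""Composite-map construction: chain pairwise transforms into global poses,
grow the canvas as frames land outside it, and composite frames in order.

The map orientation is initialized by the first frame.  Each subsequent frame
is registered against the most recent successfully registered frame; when
estimation fails the last accepted pairwise transform is inherited, so the
chain never breaks and one featureless frame costs one fallback.  When a
projected frame extends past the canvas, the canvas grows minimally and —
for growth toward negative coordinates — the cumulative offset and every
stored pose are shifted consistently.

Compositing is last-writer-wins under the frame validity mask: the canvas
shows the most recent view of each region, and poses (not pixels) are the
source of truth.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import AffineTransform, warp

from . import transforms as tf
from .config import FeatureConfig
from .features import EstimationError, FrameTransform, detect_features, match_features, estimate_affine

__all__ = [
    "Frame",
    "MapPose",
    "StitchStats",
    "BladderMap",
    "compose_global_pose",
    "expand_canvas",
    "composite_frame",
    "stitch_sequence",
    "render_map",
]


@dataclass
class Frame:
    """One (undistorted) video frame."""

    index: int
    pixels: np.ndarray  # (H, W) or (H, W, 3) uint8
    mask: np.ndarray | None = None  # bool validity grid (circular endoscope field)
    source_time: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.pixels.shape[:2]:
                raise ValueError("mask shape does not match pixel grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class MapPose:
    """Global pose of one frame in canvas coordinates."""

    frame_index: int
    matrix: np.ndarray  # 2x3, frame -> canvas
    provenance: str  # "initial" | "estimated" | "inherited"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 3)
        if self.provenance not in ("initial", "estimated", "inherited"):
            raise ValueError(f"unknown provenance {self.provenance!r}")


@dataclass
class StitchStats:
    n_frames: int = 0
    n_estimated: int = 0
    n_inherited: int = 0
    stitch_seconds: float = 0.0
    drift_seconds: float = 0.0

    def __post_init__(self) -> None:
        if min(self.n_frames, self.n_estimated, self.n_inherited) < 0:
            raise ValueError("negative counts")
        if self.n_estimated + self.n_inherited > self.n_frames:
            raise ValueError("transform counts exceed frame count")


@dataclass
class BladderMap:
    """Composite bladder map: canvas, coverage mask, per-frame poses."""

    canvas: np.ndarray
    canvas_mask: np.ndarray
    poses: list[MapPose]
    offset: np.ndarray = field(default_factory=tf.identity)
    stats: StitchStats = field(default_factory=StitchStats)
    frame_shape: tuple[int, int] | None = None
    records: list[dict] = field(default_factory=list)  # per-frame run log

    def __post_init__(self) -> None:
        self.canvas = np.asarray(self.canvas)
        self.canvas_mask = np.asarray(self.canvas_mask, dtype=bool)
        self.offset = np.asarray(self.offset, dtype=float).reshape(2, 3)

    @property
    def shape(self) -> tuple[int, int]:
        return self.canvas.shape[:2]

    def pose_of(self, frame_index: int) -> MapPose:
        for p in self.poses:
            if p.frame_index == frame_index:
                return p
        raise KeyError(f"no pose for frame {frame_index}")


def compose_global_pose(prev_pose: np.ndarray, pairwise) -> np.ndarray:
    """Compose a frame's global pose from its predecessor's pose and the
    pairwise transform (new frame -> previous frame)."""
    m = pairwise.matrix if isinstance(pairwise, FrameTransform) else pairwise
    if not (tf.is_valid_transform(prev_pose) and tf.is_valid_transform(m)):
        raise ValueError("singular or non-finite transform")
    return tf.compose(prev_pose, m)


def expand_canvas(bmap: BladderMap, corners: np.ndarray) -> BladderMap:
    """Grow the canvas minimally so that ``corners`` (canvas coords) fit.

    Growth toward negative coordinates shifts the cumulative offset and every
    stored pose by the same translation; existing content is preserved
    pixel-for-pixel.
    """
    corners = np.asarray(corners, dtype=float)
    if not np.all(np.isfinite(corners)):
        raise ValueError("non-finite corners")
    h, w = bmap.shape
    pad_left = int(max(0, np.ceil(-corners[:, 0].min())))
    pad_top = int(max(0, np.ceil(-corners[:, 1].min())))
    pad_right = int(max(0, np.ceil(corners[:, 0].max() - (w - 1))))
    pad_bottom = int(max(0, np.ceil(corners[:, 1].max() - (h - 1))))
    if not (pad_left or pad_top or pad_right or pad_bottom):
        return bmap
    pad2 = [(pad_top, pad_bottom), (pad_left, pad_right)]
    if bmap.canvas.ndim == 3:
        bmap.canvas = np.pad(bmap.canvas, pad2 + [(0, 0)])
    else:
        bmap.canvas = np.pad(bmap.canvas, pad2)
    bmap.canvas_mask = np.pad(bmap.canvas_mask, pad2)
    if pad_left or pad_top:
        delta = tf.translation(pad_left, pad_top)
        bmap.offset = tf.compose(delta, bmap.offset)
        for pose in bmap.poses:
            pose.matrix = tf.compose(delta, pose.matrix)
    return bmap


def composite_frame(bmap: BladderMap, frame: Frame, pose: np.ndarray) -> BladderMap:
    """Warp ``frame`` by ``pose`` and write it into the canvas (last writer
    wins under the validity mask).  The pose must project the frame inside
    the canvas — call :func:`expand_canvas` first."""
    pose = np.asarray(pose, dtype=float).reshape(2, 3)
    corners = tf.apply_transform(pose, tf.frame_corners(frame.shape))
    h, w = bmap.shape
    if (
        corners[:, 0].min() < -0.5
        or corners[:, 1].min() < -0.5
        or corners[:, 0].max() > w - 0.5
        or corners[:, 1].max() > h - 0.5
    ):
        raise ValueError("pose projects frame outside canvas; expand first")
    x0 = int(np.floor(corners[:, 0].min()))
    y0 = int(np.floor(corners[:, 1].min()))
    x1 = int(np.ceil(corners[:, 0].max()))
    y1 = int(np.ceil(corners[:, 1].max()))
    x0, y0 = max(0, x0), max(0, y0)
    x1, y1 = min(w - 1, x1), min(h - 1, y1)
    out_shape = (y1 - y0 + 1, x1 - x0 + 1)
    # output (bbox) coords -> frame coords
    inv = tf.compose(tf.invert(pose), tf.translation(x0, y0))
    tform = AffineTransform(matrix=tf.to_homogeneous(inv))
    warped = warp(
        frame.pixels.astype(float),
        tform,
        output_shape=out_shape,
        order=1,
        mode="constant",
        cval=0.0,
        preserve_range=True,
    )
    fmask = (
        np.ones(frame.shape, dtype=float)
        if frame.mask is None
        else frame.mask.astype(float)
    )
    wmask = warp(
        fmask, tform, output_shape=out_shape, order=1, mode="constant", cval=0.0
    )
    valid = wmask > 0.5
    region = bmap.canvas[y0 : y1 + 1, x0 : x1 + 1]
    if np.issubdtype(bmap.canvas.dtype, np.integer):
        warped = np.rint(warped)
    region[valid] = warped.astype(bmap.canvas.dtype)[valid]
    bmap.canvas_mask[y0 : y1 + 1, x0 : x1 + 1] |= valid
    return bmap


def _init_map(frame: Frame) -> BladderMap:
    mask = np.ones(frame.shape, dtype=bool) if frame.mask is None else frame.mask.copy()
    canvas = frame.pixels.copy()
    if frame.mask is not None:
        canvas = canvas * frame.mask[..., None] if canvas.ndim == 3 else canvas * frame.mask
    return BladderMap(
        canvas=canvas,
        canvas_mask=mask,
        poses=[MapPose(frame.index, tf.identity(), "initial")],
        frame_shape=frame.shape,
    )


def stitch_sequence(
    frames: list[Frame], config: FeatureConfig | None = None
) -> BladderMap:
    """Stitch an ordered, undistorted frame sequence into a bladder map.

    For each consecutive pair: detect features, match, robustly estimate the
    pairwise transform; on failure inherit the prior accepted transform.
    The per-frame log (feature/match/inlier counts and provenance) is stored
    in ``map.records``.
    """
    if not frames:
        raise ValueError("empty frame sequence")
    config = config or FeatureConfig()
    t0 = time.perf_counter()
    bmap = _init_map(frames[0])
    prev_features = detect_features(
        frames[0].pixels, frames[0].mask, config, frames[0].index
    )
    bmap.records.append(
        {
            "frame_index": frames[0].index,
            "n_features": len(prev_features),
            "n_matches": 0,
            "n_inliers": 0,
            "provenance": "initial",
        }
    )
    # the reference is the last frame that produced an accepted transform;
    # failed frames never become the reference, so one bad frame costs one
    # inherited transform, not two
    ref_features = prev_features
    ref_idx = 0  # position in bmap.poses of the reference frame
    last_pairwise = tf.identity()
    n_estimated = n_inherited = 0
    for frame in frames[1:]:
        cur_features = detect_features(frame.pixels, frame.mask, config, frame.index)
        n_matches = 0
        try:
            matches = match_features(cur_features, ref_features, config)
            n_matches = len(matches)
            pairwise = estimate_affine(matches, cur_features, ref_features, config)
            provenance, n_inl = "estimated", pairwise.inlier_count
            pose = compose_global_pose(bmap.poses[ref_idx].matrix, pairwise.matrix)
            last_pairwise = tf.compose(tf.invert(bmap.poses[-1].matrix), pose)
            n_estimated += 1
        except EstimationError:
            provenance, n_inl = "inherited", 0
            pose = compose_global_pose(bmap.poses[-1].matrix, last_pairwise)
            n_inherited += 1
        bmap.poses.append(MapPose(frame.index, pose, provenance))
        corners = tf.apply_transform(pose, tf.frame_corners(frame.shape))
        expand_canvas(bmap, corners)
        composite_frame(bmap, frame, bmap.poses[-1].matrix)
        bmap.records.append(
            {
                "frame_index": frame.index,
                "n_features": len(cur_features),
                "n_matches": n_matches,
                "n_inliers": n_inl,
                "provenance": provenance,
            }
        )
        if provenance == "estimated":
            ref_features = cur_features
            ref_idx = len(bmap.poses) - 1
    bmap.stats = StitchStats(
        n_frames=len(frames),
        n_estimated=n_estimated,
        n_inherited=n_inherited,
        stitch_seconds=time.perf_counter() - t0,
    )
    return bmap


def map_from_poses(
    frames: list[Frame],
    poses: np.ndarray,
    provenance: list[str] | None = None,
) -> BladderMap:
    """Build a map directly from known frame->canvas poses (no estimation).

    The first pose anchors the canvas.  Used by tests and by drift-correction
    round trips where poses come from elsewhere.
    """
    if len(frames) != len(poses):
        raise ValueError("frame/pose count mismatch")
    provenance = provenance or ["initial"] + ["estimated"] * (len(frames) - 1)
    bmap = BladderMap(
        canvas=np.zeros_like(frames[0].pixels),
        canvas_mask=np.zeros(frames[0].shape, dtype=bool),
        poses=[
            MapPose(f.index, np.asarray(p, dtype=float), prov)
            for f, p, prov in zip(frames, poses, provenance)
        ],
        frame_shape=frames[0].shape,
    )
    bmap.stats = StitchStats(n_frames=len(frames))
    return render_map(bmap, frames)


def render_map(bmap: BladderMap, frames: list[Frame]) -> BladderMap:
    """Re-render the canvas from the stored poses (poses are the source of
    truth; the canvas is derived).  Used after drift correction."""
    by_index = {f.index: f for f in frames}
    bmap.canvas = np.zeros_like(bmap.canvas)
    bmap.canvas_mask = np.zeros_like(bmap.canvas_mask)
    for pose in bmap.poses:
        frame = by_index[pose.frame_index]
        corners = tf.apply_transform(pose.matrix, tf.frame_corners(frame.shape))
        expand_canvas(bmap, corners)
        composite_frame(bmap, frame, pose.matrix)
    return bmap
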