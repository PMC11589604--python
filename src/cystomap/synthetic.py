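"""Synthetic ground-truth scenes for testing the stitching pipeline.

Generates vessel-textured planar surfaces (a stand-in for the mucosal
patterns the matcher keys on), scripted camera sweeps with exact
frame-to-texture similarity poses, rendered frame sequences, and synthetic
checkerboard calibration views.  Frames are similarity-warped crops of a flat
texture, so translation/rotation/zoom ground truth is exactly realizable and
pose recovery can be scored against it.

All randomness flows from a single integer seed; identical seed + parameters
yield byte-identical textures and frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import line_aa
from skimage.transform import AffineTransform, warp

from . import transforms as tf
from .calibration import CameraModel, distort_normalized, project_points, undistort_normalized
from .mapper import Frame

__all__ = [
    "RenderParams",
    "SyntheticScene",
    "generate_texture",
    "generate_trajectory",
    "make_scene",
    "render_frames",
    "generate_checkerboard_views",
]


@dataclass
class RenderParams:
    frame_size: tuple[int, int] = (200, 200)  # (height, width)
    vignette: bool = False
    noise_sigma: float = 0.0  # Gaussian noise std on [0, 1] intensities
    camera: CameraModel | None = None  # when set, frames are lens-distorted


@dataclass
class SyntheticScene:
    texture: np.ndarray  # (H, W) uint8
    seed: int
    vessel_density: float
    truth_poses: np.ndarray  # (N, 2, 3) similarity, frame -> texture
    render_params: RenderParams = field(default_factory=RenderParams)

    def __post_init__(self) -> None:
        self.truth_poses = np.asarray(self.truth_poses, dtype=float).reshape(-1, 2, 3)


def generate_texture(
    seed: int,
    size: tuple[int, int] = (1024, 1024),
    vessel_density: float = 90.0,
) -> np.ndarray:
    """Render a vessel-textured background surface.

    ``vessel_density`` is curves per megapixel.  Vessels are smoothed random
    walks with occasional branches, drawn anti-aliased in three width
    classes over a mucosa-toned background with gentle low-frequency shading
    and fine speckle, which together give blob detectors enough structure
    (the test suite verifies >= 6 features per 256x256 crop).
    """
    h, w = int(size[0]), int(size[1])
    if h < 512 or w < 512:
        raise ValueError("texture must be at least 512x512")
    rng = np.random.default_rng(seed)
    base = 0.72 + 0.07 * _smooth_noise(rng, (h, w), sigma=45.0)
    base += 0.035 * _smooth_noise(rng, (h, w), sigma=8.0)

    n_curves = int(round(vessel_density * h * w / 1e6))
    width_canvases = {1: np.zeros((h, w)), 2: np.zeros((h, w)), 3: np.zeros((h, w))}
    stack = []
    for _ in range(n_curves):
        start = rng.uniform([0, 0], [w, h])
        heading = rng.uniform(0, 2 * np.pi)
        length = int(rng.integers(120, 320))
        width = int(rng.choice([1, 1, 2, 2, 3]))
        stack.append((start, heading, length, width, True))
    while stack:
        start, heading, length, width, may_branch = stack.pop()
        pts = _random_walk(rng, start, heading, length, (w, h))
        _draw_polyline(width_canvases[width], pts)
        if may_branch and len(pts) > 40 and rng.random() < 0.6:
            k = int(rng.integers(10, len(pts) - 10))
            d = pts[k + 1] - pts[k - 1]
            branch_heading = np.arctan2(d[1], d[0]) + rng.choice([-1, 1]) * rng.uniform(
                0.6, 1.2
            )
            stack.append(
                (pts[k], branch_heading, length // 2, max(1, width - 1), False)
            )
    vessels = np.zeros((h, w))
    for width, canvas in width_canvases.items():
        vessels += gaussian_filter(np.clip(canvas, 0, 1), sigma=0.5 + 0.45 * width)
    vessels = np.clip(vessels, 0, 1)

    # sparse dark speckle: point-like features between vessels
    n_spots = n_curves * 6
    sx = rng.integers(0, w, n_spots)
    sy = rng.integers(0, h, n_spots)
    spots = np.zeros((h, w))
    spots[sy, sx] = rng.uniform(0.5, 1.0, n_spots)
    spots = gaussian_filter(spots, sigma=1.2)
    spots /= max(spots.max(), 1e-9)

    tex = np.clip(base - 0.48 * vessels - 0.22 * spots, 0.0, 1.0)
    return np.rint(tex * 255).astype(np.uint8)


def _smooth_noise(rng, shape, sigma):
    n = gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    return n / max(np.abs(n).max(), 1e-9)


def _random_walk(rng, start, heading, length, bounds):
    w, h = bounds
    step = 2.2
    pts = np.empty((length, 2))
    p = np.asarray(start, dtype=float).copy()
    for i in range(length):
        pts[i] = p
        heading += rng.normal(0.0, 0.11)
        p = p + step * np.array([np.cos(heading), np.sin(heading)])
        p[0] = np.clip(p[0], 0, w - 1)
        p[1] = np.clip(p[1], 0, h - 1)
    return pts


def _draw_polyline(canvas, pts):
    ipts = np.rint(pts).astype(int)
    keep = np.any(np.diff(ipts, axis=0, prepend=ipts[:1] - 1) != 0, axis=1)
    ipts = ipts[keep]
    h, w = canvas.shape
    for (x0, y0), (x1, y1) in zip(ipts[:-1], ipts[1:]):
        rr, cc, val = line_aa(y0, x0, y1, x1)
        keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)  # aa spills 1 px
        np.maximum.at(canvas, (rr[keep], cc[keep]), val[keep])


# ---------------------------------------------------------------------------
# Trajectories

def _pose_from_path(point, theta, scale, frame_size):
    fh, fw = frame_size
    center = np.array([(fw - 1) / 2.0, (fh - 1) / 2.0])
    lin = tf.similarity_from_params(0.0, 0.0, theta, scale)[:, :2]
    t = np.asarray(point, dtype=float) - lin @ center
    return np.column_stack([lin, t])


def _sample_polyline(waypoints, n):
    wp = np.asarray(waypoints, dtype=float)
    seg = np.linalg.norm(np.diff(wp, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, cum[-1], n)
    out = np.empty((n, 2))
    for i, s in enumerate(targets):
        k = min(np.searchsorted(cum, s, side="right") - 1, len(seg) - 1)
        frac = 0.0 if seg[k] == 0 else (s - cum[k]) / seg[k]
        out[i] = wp[k] + frac * (wp[k + 1] - wp[k])
    return out


def generate_trajectory(
    pattern: str,
    n_frames: int,
    texture_size: tuple[int, int],
    frame_size: tuple[int, int] = (200, 200),
    seed: int = 0,
    n_rows: int = 2,
    total_angle_deg: float = 40.0,
    max_step_frac: float = 0.2,
    max_span: float | None = None,
    wobble: bool = True,
) -> np.ndarray:
    """Ground-truth similarity pose sequence for a scripted sweep.

    Patterns: ``serpentine`` (alternating horizontal rows), ``longitudinal``
    (down one column and back up an adjacent, overlapping column — closes a
    loop), ``rotational`` (in-place rotation totalling ``total_angle_deg``).
    Consecutive poses keep >= 50% footprint overlap: translation steps are
    capped at ``max_step_frac`` of the frame width, rotation wobble at
    +-4 degrees, scale wobble within [0.94, 1.06].
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    th, tw = texture_size
    fh, fw = frame_size
    if fh > th or fw > tw:
        raise ValueError("frame larger than texture")
    rng = np.random.default_rng(seed)
    margin = 0.60 * float(np.hypot(fh, fw))
    cx, cy = tw / 2.0, th / 2.0
    if n_frames == 1:
        return _pose_from_path((cx, cy), 0.0, 1.0, frame_size)[None]

    if pattern == "rotational":
        thetas = np.radians(np.linspace(0.0, total_angle_deg, n_frames))
        poses = [
            _pose_from_path((cx, cy), th_i, 1.0, frame_size) for th_i in thetas
        ]
        return np.stack(poses)

    steps = n_frames - 1
    max_len = steps * max_step_frac * fw
    if pattern == "serpentine":
        usable_w = tw - 2 * margin
        usable_h = th - 2 * margin
        dy = min(0.42 * fh, usable_h / max(n_rows - 1, 1))
        span = min(usable_w, max(1.0, (max_len - (n_rows - 1) * dy) / n_rows))
        if max_span is not None:
            span = min(span, max_span)
        x0 = cx - span / 2.0
        y0 = cy - dy * (n_rows - 1) / 2.0
        waypoints = []
        for r in range(n_rows):
            xs = (x0, x0 + span) if r % 2 == 0 else (x0 + span, x0)
            waypoints.append((xs[0], y0 + r * dy))
            waypoints.append((xs[1], y0 + r * dy))
        path = _sample_polyline(waypoints, n_frames)
    elif pattern == "longitudinal":
        usable_h = th - 2 * margin
        dx = 0.30 * fw
        span = min(usable_h, max(1.0, (max_len - dx) / 2.0))
        if max_span is not None:
            span = min(span, max_span)
        xl, xr = cx - dx / 2.0, cx + dx / 2.0
        y0 = cy - span / 2.0
        waypoints = [(xl, y0), (xl, y0 + span), (xr, y0 + span), (xr, y0)]
        path = _sample_polyline(waypoints, n_frames)
    else:
        raise ValueError(f"unknown sweep pattern {pattern!r}")

    if wobble:
        ph1, ph2 = rng.uniform(0, 2 * np.pi, 2)
        i = np.arange(n_frames)
        thetas = np.radians(4.0) * np.sin(2 * np.pi * 1.5 * i / n_frames + ph1)
        scales = 1.0 + 0.05 * np.sin(2 * np.pi * 1.0 * i / n_frames + ph2)
    else:
        thetas = np.zeros(n_frames)
        scales = np.ones(n_frames)
    poses = np.stack(
        [
            _pose_from_path(path[i], thetas[i], scales[i], frame_size)
            for i in range(n_frames)
        ]
    )
    corners = tf.frame_corners(frame_size)
    for pose in poses:
        proj = tf.apply_transform(pose, corners)
        if (
            proj.min() < 0
            or proj[:, 0].max() > tw - 1
            or proj[:, 1].max() > th - 1
        ):
            raise ValueError("trajectory footprint leaves the texture")
    return poses


def make_scene(
    pattern: str = "serpentine",
    n_frames: int = 25,
    seed: int = 1,
    texture_size: tuple[int, int] = (900, 900),
    frame_size: tuple[int, int] = (200, 200),
    vessel_density: float = 90.0,
    render_params: RenderParams | None = None,
    **trajectory_kwargs,
) -> SyntheticScene:
    """Convenience constructor: texture + trajectory + render parameters."""
    texture = generate_texture(seed, texture_size, vessel_density)
    poses = generate_trajectory(
        pattern, n_frames, texture_size, frame_size, seed=seed, **trajectory_kwargs
    )
    params = render_params or RenderParams(frame_size=frame_size)
    if params.frame_size != tuple(frame_size):
        raise ValueError("render frame size disagrees with trajectory frame size")
    return SyntheticScene(texture, seed, vessel_density, poses, params)


def _vignette_mask(frame_size: tuple[int, int]) -> np.ndarray:
    fh, fw = frame_size
    yy, xx = np.mgrid[0:fh, 0:fw]
    cx, cy = (fw - 1) / 2.0, (fh - 1) / 2.0
    r = 0.48 * min(fh, fw)
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r


def render_frames(scene: SyntheticScene) -> list[Frame]:
    """Sample each frame from the texture under its ground-truth pose.

    Bilinear interpolation; optional circular vignette (dark outside the
    endoscope field, with a matching validity mask), Gaussian noise, and lens
    distortion when a camera model is set.
    """
    params = scene.render_params
    fh, fw = params.frame_size
    tex = scene.texture.astype(float) / 255.0
    th, tw = tex.shape[:2]
    corners = tf.frame_corners((fh, fw))
    noise_rng = np.random.default_rng([scene.seed, 7919])
    vmask = _vignette_mask((fh, fw)) if params.vignette else None
    frames = []
    for i, pose in enumerate(scene.truth_poses):
        proj = tf.apply_transform(pose, corners)
        if (
            proj.min() < -0.5
            or proj[:, 0].max() > tw - 0.5
            or proj[:, 1].max() > th - 0.5
        ):
            raise ValueError(f"pose {i} footprint outside texture")
        if params.camera is not None:
            img = _render_distorted(tex, pose, params.camera, (fh, fw))
        else:
            tform = AffineTransform(matrix=tf.to_homogeneous(pose))
            img = warp(
                tex, tform, output_shape=(fh, fw), order=1, mode="constant", cval=0.0
            )
        if params.noise_sigma > 0:
            img = img + noise_rng.normal(0.0, params.noise_sigma, img.shape)
        mask = None
        if vmask is not None:
            img = np.where(vmask, img, 0.02)
            mask = vmask.copy()
        pixels = np.rint(np.clip(img, 0, 1) * 255).astype(np.uint8)
        frames.append(Frame(index=i, pixels=pixels, mask=mask))
    return frames


def _render_distorted(tex, pose, camera: CameraModel, frame_size):
    from scipy.ndimage import map_coordinates

    fh, fw = frame_size
    uu, vv = np.meshgrid(np.arange(fw, dtype=float), np.arange(fh, dtype=float))
    x = (uu.ravel() - camera.principal_x) / camera.focal_x
    y = (vv.ravel() - camera.principal_y) / camera.focal_y
    und = undistort_normalized(np.column_stack([x, y]), camera.distortion)
    ideal = np.column_stack(
        [
            und[:, 0] * camera.focal_x + camera.principal_x,
            und[:, 1] * camera.focal_y + camera.principal_y,
        ]
    )
    texpts = tf.apply_transform(pose, ideal)
    return map_coordinates(
        tex, np.array([texpts[:, 1], texpts[:, 0]]), order=1, mode="constant", cval=0.0
    ).reshape(fh, fw)


# ---------------------------------------------------------------------------
# Checkerboard views

def generate_checkerboard_views(
    truth_model: CameraModel,
    n_views: int = 20,
    seed: int = 0,
    pattern_size: tuple[int, int] = (5, 7),
    square_size: float = 10.0,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Render checkerboard calibration views through a known camera.

    Returns (images, truth_corners): per view, the rendered grayscale image
    (uint8) and the exact projected positions of the inner corners, row-major
    to match :func:`~cystomap.calibration.detect_checkerboard` ordering.
    """
    if n_views < 3:
        raise ValueError("need at least 3 views")
    rng = np.random.default_rng(seed)
    cols, rows = pattern_size
    w, h = truth_model.image_size
    board_h = (rows + 1) * square_size
    # distance placing the board at ~55% of the image height
    z0 = truth_model.focal_y * board_h / (0.55 * h)
    from scipy.spatial.transform import Rotation

    obj = np.column_stack(
        [
            np.array(
                [[i * square_size, j * square_size] for j in range(rows) for i in range(cols)]
            ),
            np.zeros(cols * rows),
        ]
    )
    board_center = np.array(
        [(cols - 1) / 2.0 * square_size, (rows - 1) / 2.0 * square_size, 0.0]
    )
    images, corner_sets = [], []
    for _ in range(n_views):
        rotvec = np.array(
            [
                rng.uniform(-0.35, 0.35),
                rng.uniform(-0.35, 0.35),
                rng.uniform(-np.pi, np.pi),
            ]
        )
        rot = Rotation.from_rotvec(rotvec)
        z = z0 * rng.uniform(0.9, 1.25)
        jitter = np.array(
            [
                rng.uniform(-0.06, 0.06) * z,
                rng.uniform(-0.06, 0.06) * z,
                0.0,
            ]
        )
        tvec = np.array([0.0, 0.0, z]) + jitter - rot.apply(board_center)
        images.append(
            _render_board(truth_model, rotvec, tvec, pattern_size, square_size)
        )
        corner_sets.append(project_points(obj, rotvec, tvec, model=truth_model))
    return images, corner_sets


def _render_board(model, rotvec, tvec, pattern_size, square_size, supersample=2):
    from scipy.spatial.transform import Rotation

    cols, rows = pattern_size
    w, h = model.image_size
    ss = supersample
    uu, vv = np.meshgrid(
        (np.arange(w * ss) + 0.5) / ss - 0.5, (np.arange(h * ss) + 0.5) / ss - 0.5
    )
    x = (uu.ravel() - model.principal_x) / model.focal_x
    y = (vv.ravel() - model.principal_y) / model.focal_y
    und = undistort_normalized(np.column_stack([x, y]), model.distortion)
    rot = Rotation.from_rotvec(np.asarray(rotvec, dtype=float)).as_matrix()
    hom = np.column_stack([rot[:, 0], rot[:, 1], np.asarray(tvec, dtype=float)])
    hinv = np.linalg.inv(hom)
    rays = np.column_stack([und, np.ones(len(und))])
    board = rays @ hinv.T
    with np.errstate(divide="ignore", invalid="ignore"):
        bx = board[:, 0] / board[:, 2]
        by = board[:, 1] / board[:, 2]
    ix = np.floor(bx / square_size)
    iy = np.floor(by / square_size)
    inside = (
        (bx >= -square_size)
        & (bx <= cols * square_size)
        & (by >= -square_size)
        & (by <= rows * square_size)
        & np.isfinite(bx)
        & np.isfinite(by)
    )
    val = np.where(((ix + iy) % 2) == 0, 1.0, 0.08)
    val = np.where(inside, val, 0.62)  # gray margin outside the board
    img = val.reshape(h * ss, w * ss)
    img = img.reshape(h, ss, w, ss).mean(axis=(1, 3))
    img = gaussian_filter(img, sigma=0.6)
    return np.rint(np.clip(img, 0, 1) * 255).astype(np.uint8)
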