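"""Camera calibration from checkerboard views and lens undistortion.

Pinhole model with 5-coefficient radial/tangential distortion
(k1, k2, p1, p2, k3).  Intrinsics are initialized with the planar
(homography-based) closed form and refined jointly with per-view extrinsics
by nonlinear least squares on the reprojection error.  Only intrinsics and
distortion are persisted: stitching needs undistortion, not extrinsics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.optimize import least_squares
from scipy.spatial import ConvexHull, cKDTree
from scipy.spatial.transform import Rotation
from skimage.color import rgb2gray
from skimage.feature import corner_peaks, corner_subpix, hessian_matrix
from skimage.filters import gaussian
from skimage.transform import ProjectiveTransform
from skimage.util import img_as_float

__all__ = [
    "CameraModel",
    "CheckerboardDetection",
    "BoardNotFound",
    "CalibrationError",
    "board_object_points",
    "detect_checkerboard",
    "calibrate_camera",
    "undistort",
    "undistort_mask",
    "distort_normalized",
    "undistort_normalized",
    "project_points",
]


class CalibrationError(RuntimeError):
    """Raised for degenerate calibration geometry."""


@dataclass
class CameraModel:
    """Intrinsics + distortion of a pinhole camera."""

    focal_x: float
    focal_y: float
    principal_x: float
    principal_y: float
    distortion: np.ndarray  # (k1, k2, p1, p2, k3)
    rms_reprojection_error: float
    image_size: tuple[int, int]  # (width, height)

    def __post_init__(self) -> None:
        self.distortion = np.asarray(self.distortion, dtype=float).reshape(5)
        w, h = self.image_size
        self.image_size = (int(w), int(h))
        if self.focal_x <= 0 or self.focal_y <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.principal_x < w and 0 <= self.principal_y < h):
            raise ValueError("principal point outside image bounds")
        if self.rms_reprojection_error < 0:
            raise ValueError("negative reprojection error")

    @property
    def intrinsic_matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.focal_x, 0.0, self.principal_x],
                [0.0, self.focal_y, self.principal_y],
                [0.0, 0.0, 1.0],
            ]
        )

    def to_dict(self) -> dict:
        return {
            "fx": self.focal_x,
            "fy": self.focal_y,
            "cx": self.principal_x,
            "cy": self.principal_y,
            "dist": self.distortion.tolist(),
            "rms": self.rms_reprojection_error,
            "width": self.image_size[0],
            "height": self.image_size[1],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraModel":
        return cls(
            focal_x=d["fx"],
            focal_y=d["fy"],
            principal_x=d["cx"],
            principal_y=d["cy"],
            distortion=d["dist"],
            rms_reprojection_error=d["rms"],
            image_size=(d["width"], d["height"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "CameraModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class CheckerboardDetection:
    """Ordered subpixel inner-corner detections for one calibration view."""

    view_id: int
    corners: np.ndarray  # (cols*rows, 2) (x, y), row-major from board origin
    pattern_size: tuple[int, int]  # (cols, rows) inner corners
    square_size: float = 10.0  # mm

    def __post_init__(self) -> None:
        self.corners = np.asarray(self.corners, dtype=float).reshape(-1, 2)
        cols, rows = self.pattern_size
        if len(self.corners) != cols * rows:
            raise ValueError("corner count does not match pattern size")


@dataclass
class BoardNotFound:
    """Typed not-found result for :func:`detect_checkerboard`."""

    reason: str

    def __bool__(self) -> bool:
        return False


def board_object_points(
    pattern_size: tuple[int, int], square_size: float
) -> np.ndarray:
    """Planar (X, Y) board coordinates of the inner corners, row-major."""
    cols, rows = pattern_size
    jj, ii = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.column_stack([ii.ravel(), jj.ravel()]).astype(float) * square_size


# ---------------------------------------------------------------------------
# Checkerboard corner detection

def _xcorner_response(gray: np.ndarray, sigma: float = 2.0) -> np.ndarray:
    """Saddle-point response: strong at checkerboard X-junctions.

    X-corners are ideal intensity saddles, so the negated Hessian determinant
    responds strongly there regardless of board rotation, while plain
    L-corners at the board boundary (against the lower-contrast margin)
    respond noticeably less and are rejected by a relative threshold.
    """
    hrr, hrc, hcc = hessian_matrix(
        gray, sigma=sigma, use_gaussian_derivatives=True
    )
    return np.clip(-(hrr * hcc - hrc**2), 0.0, None)


def _fit_homography(src: np.ndarray, dst: np.ndarray) -> ProjectiveTransform | None:
    if hasattr(ProjectiveTransform, "from_estimate"):
        tform = ProjectiveTransform.from_estimate(src, dst)
        return tform if tform else None
    tform = ProjectiveTransform()
    return tform if tform.estimate(src, dst) else None


def _best_quadrilateral(points: np.ndarray) -> np.ndarray | None:
    """Maximum-area quadrilateral among convex-hull vertices (cyclic order)."""
    if len(points) < 4:
        return None
    try:
        hull = ConvexHull(points)
    except Exception:
        return None
    hv = points[hull.vertices]
    best, best_area = None, -1.0
    for idx in combinations(range(len(hv)), 4):
        quad = hv[list(idx)]
        x, y = quad[:, 0], quad[:, 1]
        area = 0.5 * abs(
            np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))
        )
        if area > best_area:
            best_area, best = area, quad
    return best


def _fit_grid(
    points: np.ndarray,
    pattern_size: tuple[int, int],
    strengths: np.ndarray | None = None,
) -> np.ndarray | None:
    """Order detected corners into a row-major grid via a homography fit.

    Tries all cyclic rotations (and the reversed cycle) of the outer
    quadrilateral as candidate board orientations, snaps predicted grid
    positions to detected corners, and keeps the valid assignment with the
    largest total saddle response.  Board-boundary L-corners lie on the same
    lattice as the inner corners, so a grid shifted by one cell can also fit
    projectively — but only the true inner grid uses exclusively strong
    X-corners, which the response score discriminates.  The 180-degree
    ordering ambiguity is resolved by whichever orientation is found first.
    """
    cols, rows = pattern_size
    quad = _best_quadrilateral(points)
    if quad is None:
        return None
    if strengths is None:
        strengths = np.ones(len(points))
    canonical = np.array(
        [[0, 0], [cols - 1, 0], [cols - 1, rows - 1], [0, rows - 1]], dtype=float
    )
    grid = board_object_points((cols, rows), 1.0)
    tree = cKDTree(points)
    best_assign, best_score = None, -np.inf
    candidates = [np.roll(quad, -k, axis=0) for k in range(4)]
    candidates += [np.roll(quad[::-1], -k, axis=0) for k in range(4)]
    for cand in candidates:
        tform = _fit_homography(canonical, cand)
        if tform is None:
            continue
        pred = tform(grid)
        spacing = np.linalg.norm(pred[1] - pred[0]) if cols > 1 else np.linalg.norm(
            pred[cols] - pred[0]
        )
        dist, idx = tree.query(pred)
        if len(np.unique(idx)) != len(grid) or dist.max() > 0.45 * spacing:
            continue
        # refine with the full correspondence set and re-snap
        tform2 = _fit_homography(grid, points[idx])
        if tform2 is not None:
            pred = tform2(grid)
            dist, idx = tree.query(pred)
            if len(np.unique(idx)) != len(grid):
                continue
        score = float(strengths[idx].sum())
        if score > best_score:
            best_score, best_assign = score, idx
    if best_assign is None:
        return None
    return points[best_assign]


def detect_checkerboard(
    image: np.ndarray,
    pattern_size: tuple[int, int] = (5, 7),
    square_size: float = 10.0,
    view_id: int = 0,
) -> CheckerboardDetection | BoardNotFound:
    """Detect the ordered inner corners of a checkerboard.

    Returns a :class:`BoardNotFound` (never raises) when the board is not
    visible; raises ``ValueError`` only for degenerate input images.
    """
    image = np.asarray(image)
    if image.ndim not in (2, 3) or min(image.shape[:2]) < 16:
        raise ValueError("empty or degenerate image")
    gray = img_as_float(rgb2gray(image) if image.ndim == 3 else image)
    smooth = gaussian(gray, sigma=1.0, preserve_range=True)
    resp = _xcorner_response(smooth)
    if resp.max() < 1e-3:
        return BoardNotFound("no corner structure")
    cols, rows = pattern_size
    n_expected = cols * rows
    peaks = corner_peaks(
        resp,
        min_distance=5,
        threshold_rel=0.25,
        num_peaks=3 * n_expected,
    )
    if len(peaks) < n_expected:
        return BoardNotFound(f"only {len(peaks)} candidate corners")
    # strongest candidates first; keep a margin for spurious responses
    strengths = resp[peaks[:, 0], peaks[:, 1]]
    order = np.argsort(strengths)[::-1][: int(1.5 * n_expected)]
    peaks, strengths = peaks[order], strengths[order]
    # X-corners respond several times stronger than board-boundary
    # L-corners; cut relative to the strongest candidates so stray boundary
    # corners cannot end up on the grid's convex hull
    ref = np.median(strengths[: min(n_expected, len(strengths))])
    strong = strengths > 0.4 * ref
    if strong.sum() >= n_expected:
        peaks, strengths = peaks[strong], strengths[strong]
    pts_xy = peaks[:, ::-1].astype(float)
    ordered = _fit_grid(pts_xy, pattern_size, strengths)
    if ordered is None and len(pts_xy) > n_expected:
        ordered = _fit_grid(
            pts_xy[:n_expected], pattern_size, strengths[:n_expected]
        )
    if ordered is None:
        return BoardNotFound("grid fit failed")
    refined = corner_subpix(gray, ordered[:, ::-1], window_size=11)
    bad = ~np.all(np.isfinite(refined), axis=1)
    refined[bad] = ordered[bad, ::-1]
    corners = refined[:, ::-1]
    h, w = gray.shape
    if np.any(corners < -1) or np.any(corners[:, 0] > w) or np.any(corners[:, 1] > h):
        return BoardNotFound("corners outside image bounds")
    return CheckerboardDetection(view_id, corners, pattern_size, square_size)


# ---------------------------------------------------------------------------
# Distortion model

def distort_normalized(pts: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Apply the 5-coefficient distortion model to normalized (x, y) points."""
    k1, k2, p1, p2, k3 = dist
    x, y = pts[:, 0], pts[:, 1]
    r2 = x * x + y * y
    radial = 1.0 + k1 * r2 + k2 * r2**2 + k3 * r2**3
    xd = x * radial + 2 * p1 * x * y + p2 * (r2 + 2 * x * x)
    yd = y * radial + p1 * (r2 + 2 * y * y) + 2 * p2 * x * y
    return np.column_stack([xd, yd])


def undistort_normalized(
    pts: np.ndarray, dist: np.ndarray, n_iter: int = 12
) -> np.ndarray:
    """Invert the distortion model by fixed-point iteration."""
    k1, k2, p1, p2, k3 = dist
    xd, yd = pts[:, 0], pts[:, 1]
    x, y = xd.copy(), yd.copy()
    for _ in range(n_iter):
        r2 = x * x + y * y
        radial = 1.0 + k1 * r2 + k2 * r2**2 + k3 * r2**3
        dx = 2 * p1 * x * y + p2 * (r2 + 2 * x * x)
        dy = p1 * (r2 + 2 * y * y) + 2 * p2 * x * y
        x = (xd - dx) / radial
        y = (yd - dy) / radial
    return np.column_stack([x, y])


def project_points(
    object_pts: np.ndarray,
    rvec: np.ndarray,
    tvec: np.ndarray,
    model: CameraModel | None = None,
    intrinsics: np.ndarray | None = None,
    dist: np.ndarray | None = None,
) -> np.ndarray:
    """Project 3D object points to pixels through rotation, translation,
    distortion, and intrinsics."""
    if model is not None:
        intrinsics = model.intrinsic_matrix
        dist = model.distortion
    pts = np.asarray(object_pts, dtype=float)
    if pts.shape[1] == 2:
        pts = np.column_stack([pts, np.zeros(len(pts))])
    cam = Rotation.from_rotvec(np.asarray(rvec, dtype=float)).apply(pts) + np.asarray(
        tvec, dtype=float
    )
    norm = cam[:, :2] / cam[:, 2:3]
    nd = distort_normalized(norm, np.asarray(dist, dtype=float))
    fx, fy = intrinsics[0, 0], intrinsics[1, 1]
    cx, cy = intrinsics[0, 2], intrinsics[1, 2]
    return np.column_stack([fx * nd[:, 0] + cx, fy * nd[:, 1] + cy])


# ---------------------------------------------------------------------------
# Zhang-style closed-form initialization

def _homographies(detections, square_size):
    hs = []
    for det in detections:
        obj = board_object_points(det.pattern_size, square_size)
        tform = _fit_homography(obj, det.corners)
        if tform is None:
            raise CalibrationError(f"homography failed for view {det.view_id}")
        hs.append(tform.params / tform.params[2, 2])
    return hs


def _v_ij(h: np.ndarray, i: int, j: int) -> np.ndarray:
    return np.array(
        [
            h[0, i] * h[0, j],
            h[0, i] * h[1, j] + h[1, i] * h[0, j],
            h[1, i] * h[1, j],
            h[2, i] * h[0, j] + h[0, i] * h[2, j],
            h[2, i] * h[1, j] + h[1, i] * h[2, j],
            h[2, i] * h[2, j],
        ]
    )


def _closed_form_intrinsics(hs: list[np.ndarray]) -> np.ndarray:
    rows = []
    for h in hs:
        rows.append(_v_ij(h, 0, 1))
        rows.append(_v_ij(h, 0, 0) - _v_ij(h, 1, 1))
    v = np.asarray(rows)
    _, _, vt = np.linalg.svd(v)
    b11, b12, b22, b13, b23, b33 = vt[-1]
    denom = b11 * b22 - b12**2
    if abs(denom) < 1e-16 or abs(b11) < 1e-16:
        raise CalibrationError("degenerate view geometry (poses too similar)")
    v0 = (b12 * b13 - b11 * b23) / denom
    lam = b33 - (b13**2 + v0 * (b12 * b13 - b11 * b23)) / b11
    fx2 = lam / b11
    fy2 = lam * b11 / denom
    if fx2 <= 0 or fy2 <= 0:
        raise CalibrationError("degenerate view geometry (poses too similar)")
    fx, fy = np.sqrt(fx2), np.sqrt(fy2)
    skew = -b12 * fx2 * fy / lam
    u0 = skew * v0 / fy - b13 * fx2 / lam
    return np.array([[fx, 0.0, u0], [0.0, fy, v0], [0.0, 0.0, 1.0]])


def _extrinsics_from_homography(h: np.ndarray, k: np.ndarray):
    kinv = np.linalg.inv(k)
    lam = 1.0 / np.linalg.norm(kinv @ h[:, 0])
    t = lam * (kinv @ h[:, 2])
    if t[2] < 0:
        lam, t = -lam, -t
    r1 = lam * (kinv @ h[:, 0])
    r2 = lam * (kinv @ h[:, 1])
    r3 = np.cross(r1, r2)
    rot = np.column_stack([r1, r2, r3])
    u, _, vt = np.linalg.svd(rot)
    rot = u @ vt
    if np.linalg.det(rot) < 0:
        rot = u @ np.diag([1.0, 1.0, -1.0]) @ vt
    return Rotation.from_matrix(rot).as_rotvec(), t


def calibrate_camera(
    detections: list[CheckerboardDetection],
    square_size: float = 10.0,
    image_size: tuple[int, int] | None = None,
) -> CameraModel:
    """Estimate intrinsics and distortion from >= 3 checkerboard views.

    Raises ``ValueError`` for too few views and :class:`CalibrationError`
    for degenerate geometry.
    """
    if len(detections) < 3:
        raise ValueError(f"need at least 3 views, got {len(detections)}")
    if image_size is None:
        raise ValueError("image_size is required")
    hs = _homographies(detections, square_size)
    k0 = _closed_form_intrinsics(hs)
    extr0 = [_extrinsics_from_homography(h, k0) for h in hs]

    obj = [
        board_object_points(d.pattern_size, square_size) for d in detections
    ]
    observed = np.concatenate([d.corners for d in detections])

    def pack(k, dist, extr):
        p = [k[0, 0], k[1, 1], k[0, 2], k[1, 2], *dist]
        for rvec, tvec in extr:
            p.extend(rvec)
            p.extend(tvec)
        return np.asarray(p, dtype=float)

    def unpack(p):
        fx, fy, cx, cy = p[:4]
        dist = p[4:9]
        extr = [(p[9 + 6 * i : 12 + 6 * i], p[12 + 6 * i : 15 + 6 * i]) for i in range(len(detections))]
        kmat = np.array([[fx, 0, cx], [0, fy, cy], [0, 0, 1.0]])
        return kmat, dist, extr

    def residuals(p):
        kmat, dist, extr = unpack(p)
        proj = np.concatenate(
            [
                project_points(o, rvec, tvec, intrinsics=kmat, dist=dist)
                for o, (rvec, tvec) in zip(obj, extr)
            ]
        )
        return (proj - observed).ravel()

    x0 = pack(k0, np.zeros(5), extr0)
    sol = least_squares(residuals, x0, method="lm", max_nfev=400)
    kmat, dist, _ = unpack(sol.x)
    res = sol.fun.reshape(-1, 2)
    rms = float(np.sqrt(np.mean(np.sum(res**2, axis=1))))
    w, h = image_size
    cx = float(np.clip(kmat[0, 2], 0, w - 1))
    cy = float(np.clip(kmat[1, 2], 0, h - 1))
    return CameraModel(
        focal_x=float(kmat[0, 0]),
        focal_y=float(kmat[1, 1]),
        principal_x=cx,
        principal_y=cy,
        distortion=dist,
        rms_reprojection_error=rms,
        image_size=(w, h),
    )


# ---------------------------------------------------------------------------
# Undistortion

def _undistort_source_coords(model: CameraModel) -> tuple[np.ndarray, np.ndarray]:
    w, h = model.image_size
    uu, vv = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    x = (uu - model.principal_x) / model.focal_x
    y = (vv - model.principal_y) / model.focal_y
    nd = distort_normalized(
        np.column_stack([x.ravel(), y.ravel()]), model.distortion
    )
    us = (model.focal_x * nd[:, 0] + model.principal_x).reshape(h, w)
    vs = (model.focal_y * nd[:, 1] + model.principal_y).reshape(h, w)
    return us, vs


def undistort(image: np.ndarray, model: CameraModel) -> np.ndarray:
    """Resample an image onto the ideal (distortion-free) pixel grid.

    Bilinear interpolation; pixels mapping outside the source are 0.  Output
    has the same shape and dtype as the input.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    if (w, h) != model.image_size:
        raise ValueError(
            f"image size {(w, h)} does not match model {model.image_size}"
        )
    us, vs = _undistort_source_coords(model)
    coords = np.array([vs, us])

    def sample(channel):
        return map_coordinates(
            channel.astype(float), coords, order=1, mode="constant", cval=0.0
        )

    if image.ndim == 2:
        out = sample(image)
    else:
        out = np.stack([sample(image[..., c]) for c in range(image.shape[2])], axis=-1)
    if np.issubdtype(image.dtype, np.integer):
        out = np.rint(out)
    return out.astype(image.dtype)


def undistort_mask(model: CameraModel, mask: np.ndarray | None = None) -> np.ndarray:
    """Validity mask after undistortion: True where source pixels exist."""
    w, h = model.image_size
    us, vs = _undistort_source_coords(model)
    valid = (us >= 0) & (us <= w - 1) & (vs >= 0) & (vs <= h - 1)
    if mask is not None:
        coords = np.array([vs, us])
        src = map_coordinates(
            np.asarray(mask, dtype=float), coords, order=1, mode="constant", cval=0.0
        )
        valid &= src > 0.5
    return valid
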