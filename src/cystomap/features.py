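"""Per-frame feature detection, brute-force matching, and robust pairwise
transform estimation.

The pairwise transform between consecutive frames is estimated with a seeded
RANSAC over a 4-DOF similarity (default) or 6-DOF affine model, followed by a
least-squares refit on the inlier set.  A frame pair is only accepted when at
least ``min_features`` keypoints were detected in each frame AND at least
``min_inliers`` correspondences survive the robust fit; otherwise a typed
:class:`EstimationError` is raised and the caller falls back to the previously
accepted transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2gray
from skimage.feature import SIFT, match_descriptors
from skimage.util import img_as_float

from .config import FeatureConfig
from .transforms import apply_transform

__all__ = [
    "FeatureSet",
    "MatchSet",
    "FrameTransform",
    "EstimationError",
    "detect_features",
    "match_features",
    "estimate_affine",
]


class EstimationError(RuntimeError):
    """Raised when a pairwise transform cannot be estimated.

    Carries a machine-readable ``reason`` so run logs can report why a frame
    fell back to the inherited transform.
    """

    def __init__(self, reason: str, message: str = ""):
        self.reason = reason
        super().__init__(message or reason)


@dataclass
class FeatureSet:
    """Keypoints + descriptors detected on one frame.

    ``keypoints`` is (N, 4): x, y in pixels, scale in pixels, orientation in
    radians.  ``descriptors`` is (N, D).
    """

    frame_index: int
    keypoints: np.ndarray
    descriptors: np.ndarray

    def __post_init__(self) -> None:
        self.keypoints = np.asarray(self.keypoints, dtype=float).reshape(-1, 4)
        self.descriptors = np.asarray(self.descriptors)
        if len(self.keypoints) != len(self.descriptors):
            raise ValueError("keypoint/descriptor count mismatch")

    def __len__(self) -> int:
        return len(self.keypoints)

    @property
    def positions(self) -> np.ndarray:
        """(N, 2) array of (x, y) keypoint positions."""
        return self.keypoints[:, :2]


@dataclass
class MatchSet:
    """Candidate correspondences between two feature sets."""

    pairs: np.ndarray  # (M, 2) indices (index_a, index_b)
    distances: np.ndarray  # (M,) descriptor distances
    inlier_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.distances = np.asarray(self.distances, dtype=float).reshape(-1)
        if self.inlier_flags is None:
            self.inlier_flags = np.zeros(len(self.pairs), dtype=bool)
        self.inlier_flags = np.asarray(self.inlier_flags, dtype=bool).reshape(-1)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def n_inliers(self) -> int:
        return int(self.inlier_flags.sum())


@dataclass
class FrameTransform:
    """Pairwise affine between two frames.

    ``matrix`` (2x3) maps source-frame pixel coordinates to target-frame
    coordinates.  ``provenance`` records whether the transform was estimated
    from matched features or inherited from the prior accepted transform when
    estimation failed.
    """

    matrix: np.ndarray
    source_index: int
    target_index: int
    provenance: str = "estimated"  # "estimated" | "inherited"
    inlier_count: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 3)
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("non-finite transform matrix")
        if abs(np.linalg.det(self.matrix[:, :2])) <= 1e-12:
            raise ValueError("singular transform matrix")
        if self.provenance not in ("estimated", "inherited"):
            raise ValueError(f"unknown provenance {self.provenance!r}")


def _as_gray_float(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim == 3:
        image = rgb2gray(image)
    return img_as_float(image)


def detect_features(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    config: FeatureConfig | None = None,
    frame_index: int = -1,
) -> FeatureSet:
    """Detect keypoints and descriptors on a single frame.

    Keypoints outside ``mask`` (when given) are discarded.  The result is
    deterministic for a fixed input and config; keypoints are sorted by
    detection scale (largest first) with a positional tie-break.  An empty
    :class:`FeatureSet` is a valid result for structureless images.
    """
    config = config or FeatureConfig()
    if config.detector != "sift":
        raise ValueError(f"unknown detector {config.detector!r}")
    gray = _as_gray_float(image)
    detector = SIFT(**config.detector_params)
    try:
        detector.detect_and_extract(gray)
    except RuntimeError:  # skimage raises when no keypoints survive
        return FeatureSet(frame_index, np.empty((0, 4)), np.empty((0, 128)))
    xy = detector.positions[:, ::-1].astype(float)  # (row, col) -> (x, y)
    kps = np.column_stack(
        [xy, detector.sigmas.astype(float), detector.orientations.astype(float)]
    )
    desc = detector.descriptors.astype(float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        cols = np.clip(np.round(xy[:, 0]).astype(int), 0, mask.shape[1] - 1)
        rows = np.clip(np.round(xy[:, 1]).astype(int), 0, mask.shape[0] - 1)
        keep = mask[rows, cols]
        kps, desc = kps[keep], desc[keep]
    order = np.lexsort((kps[:, 0], kps[:, 1], -kps[:, 2]))
    return FeatureSet(frame_index, kps[order], desc[order])


def match_features(
    a: FeatureSet, b: FeatureSet, config: FeatureConfig | None = None
) -> MatchSet:
    """Brute-force descriptor matching with a Lowe ratio test.

    Returns candidate pairs only; ``inlier_flags`` are all false until
    :func:`estimate_affine` runs.  Either set being empty yields an empty
    MatchSet.
    """
    config = config or FeatureConfig()
    if len(a) == 0 or len(b) == 0:
        return MatchSet(np.empty((0, 2), dtype=int), np.empty(0))
    if a.descriptors.shape[1] != b.descriptors.shape[1]:
        raise ValueError("descriptor dimensionality mismatch")
    pairs = match_descriptors(
        a.descriptors,
        b.descriptors,
        cross_check=config.cross_check,
        max_ratio=config.ratio,
    )
    da = a.descriptors[pairs[:, 0]].astype(float)
    db = b.descriptors[pairs[:, 1]].astype(float)
    distances = np.linalg.norm(da - db, axis=1)
    return MatchSet(pairs, distances)


# ---------------------------------------------------------------------------
# Robust similarity / affine fitting

def _fit_similarity(src: np.ndarray, dst: np.ndarray) -> np.ndarray | None:
    """Least-squares similarity (Umeyama, uniform scale) mapping src -> dst."""
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    cs, cd = src - mu_s, dst - mu_d
    var_s = (cs**2).sum() / len(src)
    if var_s < 1e-12:
        return None
    cov = cd.T @ cs / len(src)
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    dmat = np.diag([1.0, d])
    rot = u @ dmat @ vt
    scale = float(np.trace(np.diag(s) @ dmat)) / var_s
    if scale <= 1e-12:
        return None
    t = mu_d - scale * rot @ mu_s
    return np.column_stack([scale * rot, t])


def _fit_affine(src: np.ndarray, dst: np.ndarray) -> np.ndarray | None:
    """Least-squares full affine mapping src -> dst."""
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    design = np.column_stack([src, np.ones(len(src))])
    coef, _, rank, _ = np.linalg.lstsq(design, dst, rcond=None)
    if rank < 3:
        return None
    m = coef.T  # (2, 3): [[a, b, tx], [c, d, ty]]
    if abs(np.linalg.det(m[:, :2])) <= 1e-12:
        return None
    return m


_FITTERS = {"similarity": (_fit_similarity, 2), "affine": (_fit_affine, 3)}


def _ransac(
    src: np.ndarray,
    dst: np.ndarray,
    model: str,
    threshold: float,
    confidence: float,
    max_iters: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray | None, np.ndarray]:
    fit, min_samples = _FITTERS[model]
    n = len(src)
    best_inliers = np.zeros(n, dtype=bool)
    best_count = 0
    n_iters = max_iters
    i = 0
    while i < n_iters and i < max_iters:
        idx = rng.choice(n, size=min_samples, replace=False)
        m = fit(src[idx], dst[idx])
        i += 1
        if m is None:
            continue
        resid = np.linalg.norm(apply_transform(m, src) - dst, axis=1)
        inliers = resid < threshold
        count = int(inliers.sum())
        if count > best_count:
            best_count, best_inliers = count, inliers
            ratio = count / n
            if ratio >= 1.0:
                break
            # adaptive stopping: iterations needed for the target confidence
            denom = np.log1p(-(ratio**min_samples))
            if denom < 0:
                n_iters = min(max_iters, int(np.ceil(np.log(1 - confidence) / denom)))
    if best_count < min_samples:
        return None, best_inliers
    m = fit(src[best_inliers], dst[best_inliers])
    if m is None:
        return None, best_inliers
    resid = np.linalg.norm(apply_transform(m, src) - dst, axis=1)
    inliers = resid < threshold
    m = fit(src[inliers], dst[inliers]) if inliers.sum() >= min_samples else None
    return m, inliers


def estimate_affine(
    matches: MatchSet,
    a: FeatureSet,
    b: FeatureSet,
    config: FeatureConfig | None = None,
) -> FrameTransform:
    """Robustly estimate the transform mapping frame ``a`` coords to frame ``b``.

    Applies the feature gate (>= ``min_features`` keypoints in each frame),
    runs seeded RANSAC over the candidate matches, refits on the inlier set,
    and updates ``matches.inlier_flags`` in place.

    Raises
    ------
    EstimationError
        When the gate fails, there are too few matches, or fewer than
        ``min_inliers`` correspondences survive.  The caller is expected to
        fall back to the prior accepted transform.
    """
    config = config or FeatureConfig()
    rc = config.ransac
    if len(a) < config.min_features or len(b) < config.min_features:
        raise EstimationError(
            "feature_gate",
            f"feature gate failed: {len(a)} / {len(b)} keypoints "
            f"(minimum {config.min_features} each)",
        )
    _, min_samples = _FITTERS[config.model]
    if len(matches) < max(min_samples, rc.min_inliers):
        raise EstimationError(
            "too_few_matches", f"{len(matches)} matches < minimum {rc.min_inliers}"
        )
    src = a.positions[matches.pairs[:, 0]]
    dst = b.positions[matches.pairs[:, 1]]
    rng = np.random.default_rng(rc.seed)
    m, inliers = _ransac(
        src, dst, config.model, rc.threshold_px, rc.confidence, rc.max_iters, rng
    )
    matches.inlier_flags = inliers
    n_inliers = int(inliers.sum())
    if m is None or n_inliers < rc.min_inliers:
        raise EstimationError(
            "too_few_inliers", f"{n_inliers} inliers < minimum {rc.min_inliers}"
        )
    return FrameTransform(
        matrix=m,
        source_index=a.frame_index,
        target_index=b.frame_index,
        provenance="estimated",
        inlier_count=n_inliers,
    )
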