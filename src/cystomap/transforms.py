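"""2D affine / similarity transform utilities.

All transforms are 2x3 float64 row-major matrices ``[[a, b, tx], [c, d, ty]]``
acting on homogeneous column vectors ``(x, y, 1)``; pixel coordinates have the
origin at the top-left corner, x pointing right, y pointing down, 0-based.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "identity",
    "to_homogeneous",
    "from_homogeneous",
    "compose",
    "invert",
    "apply_transform",
    "translation",
    "similarity_from_params",
    "similarity_params",
    "frame_corners",
    "is_valid_transform",
]


def identity() -> np.ndarray:
    """Return the 2x3 identity transform."""
    return np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])


def to_homogeneous(m: np.ndarray) -> np.ndarray:
    """Lift a 2x3 matrix to its 3x3 homogeneous form."""
    m = np.asarray(m, dtype=float)
    if m.shape == (3, 3):
        return m
    if m.shape != (2, 3):
        raise ValueError(f"expected 2x3 transform, got shape {m.shape}")
    return np.vstack([m, [0.0, 0.0, 1.0]])


def from_homogeneous(m: np.ndarray) -> np.ndarray:
    """Drop the last row of a 3x3 homogeneous affine matrix."""
    m = np.asarray(m, dtype=float)
    if m.shape == (2, 3):
        return m
    if m.shape != (3, 3):
        raise ValueError(f"expected 3x3 matrix, got shape {m.shape}")
    return m[:2, :].copy()


def compose(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Return the composition ``a @ b`` (apply ``b`` first, then ``a``)."""
    return from_homogeneous(to_homogeneous(a) @ to_homogeneous(b))


def invert(m: np.ndarray) -> np.ndarray:
    """Invert an affine transform.  Raises ``np.linalg.LinAlgError`` if singular."""
    return from_homogeneous(np.linalg.inv(to_homogeneous(m)))


def apply_transform(m: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Apply a 2x3 transform to an (N, 2) array of (x, y) points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    m = np.asarray(m, dtype=float)
    return pts @ m[:, :2].T + m[:, 2]


def translation(tx: float, ty: float) -> np.ndarray:
    """Pure-translation transform."""
    return np.array([[1.0, 0.0, float(tx)], [0.0, 1.0, float(ty)]])


def similarity_from_params(
    tx: float, ty: float, theta: float, scale: float
) -> np.ndarray:
    """Build a similarity transform from translation, rotation (rad), uniform scale."""
    c, s = np.cos(theta) * scale, np.sin(theta) * scale
    return np.array([[c, -s, float(tx)], [s, c, float(ty)]])


def similarity_params(m: np.ndarray) -> tuple[float, float, float, float]:
    """Decompose a transform into (tx, ty, theta, scale).

    For non-similarity affines this returns the closest similarity parameters
    (rotation angle from the polar decomposition, scale as the geometric mean
    of the singular values).
    """
    m = np.asarray(m, dtype=float)
    a_lin = m[:2, :2]
    theta = float(np.arctan2(a_lin[1, 0] - a_lin[0, 1], a_lin[0, 0] + a_lin[1, 1]))
    scale = float(np.sqrt(abs(np.linalg.det(a_lin))))
    return float(m[0, 2]), float(m[1, 2]), theta, scale


def frame_corners(shape: tuple[int, ...]) -> np.ndarray:
    """Corner (x, y) coordinates of an image of the given array ``shape``.

    Corners are pixel-center based: (0, 0) .. (W-1, H-1), counter-clockwise
    starting at the top-left.
    """
    h, w = int(shape[0]), int(shape[1])
    return np.array(
        [[0.0, 0.0], [w - 1.0, 0.0], [w - 1.0, h - 1.0], [0.0, h - 1.0]]
    )


def is_valid_transform(m: np.ndarray) -> bool:
    """True when finite with a non-singular linear part."""
    m = np.asarray(m, dtype=float)
    if m.shape not in ((2, 3), (3, 3)):
        return False
    if not np.all(np.isfinite(m)):
        return False
    return abs(float(np.linalg.det(m[:2, :2]))) > 1e-12
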