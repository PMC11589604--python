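"""Frame ingestion, map persistence, and run manifests.

Maps are persisted as a directory: ``canvas.png`` + ``canvas_mask.png``
(lossless PNG), ``poses.json`` (versioned schema, row-major 6-element
matrices), and ``stats.json``.  ``load(write(m))`` reproduces poses exactly
and canvas pixels bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import binary_fill_holes, label
from skimage.color import rgb2gray
from skimage.filters import gaussian
from skimage.util import img_as_float

from .mapper import BladderMap, Frame, MapPose, StitchStats

__all__ = [
    "FormatError",
    "RunManifest",
    "read_frames",
    "detect_circular_mask",
    "write_map",
    "load_map",
    "write_frame_log",
]

POSE_SCHEMA_VERSION = 1
IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}
VIDEO_EXTENSIONS = {".mp4", ".avi", ".mov", ".mkv"}


class FormatError(ValueError):
    """A map directory is missing or has a corrupt artifact."""


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-for-bit."""

    inputs: list[str] = field(default_factory=list)
    camera: str | None = None
    config: dict = field(default_factory=dict)
    stride: int = 1
    crop: int | None = None
    seed: int = 0
    outputs: list[str] = field(default_factory=list)
    stats: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _crop_center(img: np.ndarray, crop: int) -> np.ndarray:
    h, w = img.shape[:2]
    if crop > min(h, w):
        raise ValueError(f"crop {crop} larger than frame {h}x{w}")
    y0 = (h - crop) // 2
    x0 = (w - crop) // 2
    return img[y0 : y0 + crop, x0 : x0 + crop]


def detect_circular_mask(image: np.ndarray, threshold: float = 0.06) -> np.ndarray:
    """Estimate the circular endoscope field by thresholding near-black
    borders; keeps the largest bright connected component."""
    gray = img_as_float(rgb2gray(image) if np.asarray(image).ndim == 3 else image)
    bright = gaussian(gray, sigma=3, preserve_range=True) > threshold
    labels, n = label(bright)
    if n == 0:
        return np.ones_like(bright, dtype=bool)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return binary_fill_holes(labels == largest)


def read_frames(
    path: str | Path,
    stride: int = 1,
    crop: int | None = None,
    mask: str = "none",
) -> list[Frame]:
    """Load an ordered frame sequence from an image directory or video file.

    ``stride`` keeps every stride-th source frame; ``Frame.index`` reflects
    the source position.  ``crop`` takes a centered square of that size.
    ``mask``: "none" or "auto" (circular endoscope-field detection).
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such input: {path}")
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in IMAGE_EXTENSIONS
        )
        if not files:
            raise IOError(f"no image files in {path}")
        raw = ((i, iio.imread(f)) for i, f in enumerate(files))
    elif path.suffix.lower() in VIDEO_EXTENSIONS:
        try:
            raw = enumerate(iio.imiter(path))
        except Exception as err:  # missing ffmpeg plugin, corrupt file, ...
            raise IOError(f"cannot read video {path}: {err}") from err
    else:
        raw = [(0, iio.imread(path))]
    frames = []
    for i, img in raw:
        if i % stride:
            continue
        if crop is not None:
            img = _crop_center(img, crop)
        m = detect_circular_mask(img) if mask == "auto" else None
        frames.append(Frame(index=i, pixels=np.asarray(img), mask=m))
    return frames


def write_map(bmap: BladderMap, mapdir: str | Path) -> None:
    mapdir = Path(mapdir)
    mapdir.mkdir(parents=True, exist_ok=True)
    iio.imwrite(mapdir / "canvas.png", bmap.canvas)
    iio.imwrite(
        mapdir / "canvas_mask.png", (bmap.canvas_mask * np.uint8(255))
    )
    poses = {
        "schema_version": POSE_SCHEMA_VERSION,
        "convention": "row-major 2x3 [[a,b,tx],[c,d,ty]] on (x,y,1); origin top-left",
        "frame_shape": list(bmap.frame_shape) if bmap.frame_shape else None,
        "offset": bmap.offset.ravel().tolist(),
        "poses": [
            {
                "frame_index": p.frame_index,
                "matrix": p.matrix.ravel().tolist(),
                "provenance": p.provenance,
            }
            for p in bmap.poses
        ],
    }
    (mapdir / "poses.json").write_text(json.dumps(poses, indent=2))
    (mapdir / "stats.json").write_text(
        json.dumps(dataclasses.asdict(bmap.stats), indent=2)
    )
    if bmap.records:
        write_frame_log(bmap.records, mapdir / "frames.log")


def load_map(mapdir: str | Path) -> BladderMap:
    mapdir = Path(mapdir)
    for name in ("canvas.png", "canvas_mask.png", "poses.json", "stats.json"):
        if not (mapdir / name).exists():
            raise FormatError(f"map directory {mapdir} is missing {name}")
    canvas = iio.imread(mapdir / "canvas.png")
    canvas_mask = iio.imread(mapdir / "canvas_mask.png") > 127
    meta = json.loads((mapdir / "poses.json").read_text())
    if meta.get("schema_version") != POSE_SCHEMA_VERSION:
        raise FormatError(f"unsupported pose schema in {mapdir}")
    poses = [
        MapPose(
            frame_index=p["frame_index"],
            matrix=np.asarray(p["matrix"], dtype=float).reshape(2, 3),
            provenance=p["provenance"],
        )
        for p in meta["poses"]
    ]
    stats = StitchStats(**json.loads((mapdir / "stats.json").read_text()))
    frame_shape = tuple(meta["frame_shape"]) if meta.get("frame_shape") else None
    return BladderMap(
        canvas=canvas,
        canvas_mask=canvas_mask,
        poses=poses,
        offset=np.asarray(meta["offset"], dtype=float).reshape(2, 3),
        stats=stats,
        frame_shape=frame_shape,
    )


def write_frame_log(records: list[dict], path: str | Path) -> None:
    """One machine-parsable JSON line per frame: index, feature count, match
    count, inliers, provenance — the data behind success-rate reporting."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")
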