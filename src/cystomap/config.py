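"""Run configuration objects and YAML/JSON (de)serialization."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RansacConfig", "FeatureConfig", "load_config", "save_config"]


@dataclass
class RansacConfig:
    """Robust-estimation parameters.

    ``min_inliers`` mirrors the per-frame feature gate: a transform is only
    accepted when at least this many correspondences survive.
    """

    threshold_px: float = 3.0
    confidence: float = 0.995
    max_iters: int = 2000
    min_inliers: int = 6
    seed: int = 0


@dataclass
class FeatureConfig:
    """Detector, matcher, and transform-model configuration.

    The detector is a pluggable strategy; the default is a scale- and
    rotation-invariant blob detector with floating-point-style descriptors
    (SIFT as shipped by scikit-image).  ``model`` selects the pairwise
    transform family: a 4-DOF similarity (translation, rotation, uniform
    zoom) by default, or a full 6-DOF affine.
    """

    detector: str = "sift"
    detector_params: dict = field(default_factory=dict)
    ratio: float = 0.75
    cross_check: bool = True
    min_features: int = 6
    model: str = "similarity"  # "similarity" | "affine"
    ransac: RansacConfig = field(default_factory=RansacConfig)

    def __post_init__(self) -> None:
        if self.model not in ("similarity", "affine"):
            raise ValueError(f"unknown transform model {self.model!r}")
        if isinstance(self.ransac, dict):
            self.ransac = RansacConfig(**self.ransac)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        return cls(**d)


def load_config(path: str | Path) -> FeatureConfig:
    """Load a :class:`FeatureConfig` from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return FeatureConfig.from_dict(data or {})


def save_config(config: FeatureConfig, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(config.to_dict(), indent=2))
    else:
        path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
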