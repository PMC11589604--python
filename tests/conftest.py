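"""Session-scoped synthetic fixtures shared across the suite.

Everything is generated programmatically from fixed seeds; no binary data
ships with the repository.
"""

from __future__ import annotations

import numpy as np
import pytest

from cystomap import transforms as tf
from cystomap.calibration import CameraModel
from cystomap.drift import find_spatial_neighbors, measure_loop_residuals
from cystomap.mapper import map_from_poses, stitch_sequence
from cystomap.synthetic import (
    RenderParams,
    SyntheticScene,
    generate_checkerboard_views,
    generate_texture,
    generate_trajectory,
    make_scene,
    render_frames,
)

from helpers import biased_chain

FRAME_SHAPE = (200, 200)
TEXTURE_SHAPE = (900, 900)


@pytest.fixture(scope="session")
def scene25() -> SyntheticScene:
    """25-frame serpentine sweep over the default vessel texture, seed 1."""
    return make_scene(
        pattern="serpentine",
        n_frames=25,
        seed=1,
        texture_size=TEXTURE_SHAPE,
        frame_size=FRAME_SHAPE,
    )


@pytest.fixture(scope="session")
def frames25(scene25):
    return render_frames(scene25)


@pytest.fixture(scope="session")
def map25(scene25, frames25):
    return stitch_sequence(frames25)


@pytest.fixture(scope="session")
def revisit_case(scene25, map25):
    """Revisit sweep over the same texture along a new (bounded) path."""
    poses = generate_trajectory(
        "longitudinal",
        20,
        TEXTURE_SHAPE,
        FRAME_SHAPE,
        seed=5,
        max_span=70,
    )
    scene = SyntheticScene(
        scene25.texture, 5, scene25.vessel_density, poses,
        RenderParams(frame_size=FRAME_SHAPE),
    )
    return {"scene": scene, "frames": render_frames(scene), "poses": poses}


@pytest.fixture(scope="session")
def drift_case(scene25):
    """30-frame loop-closing sweep with a +0.2 px/step translation bias.

    Returns the frames, the ground-truth canvas poses, the biased map, and
    the measured closures (before correction).
    """
    poses = generate_trajectory(
        "longitudinal", 30, TEXTURE_SHAPE, FRAME_SHAPE, seed=3
    )
    scene = SyntheticScene(
        scene25.texture, 3, scene25.vessel_density, poses,
        RenderParams(frame_size=FRAME_SHAPE),
    )
    frames = render_frames(scene)
    truth_canvas = np.stack(
        [tf.compose(tf.invert(poses[0]), p) for p in poses]
    )
    bmap = map_from_poses(frames, biased_chain(poses, bias=(0.2, 0.0)))
    pairs = find_spatial_neighbors(bmap, min_gap=10)
    closures = measure_loop_residuals(pairs, frames, bmap)
    return {
        "frames": frames,
        "truth_poses": poses,
        "truth_canvas": truth_canvas,
        "map": bmap,
        "pairs": pairs,
        "closures": closures,
    }


@pytest.fixture(scope="session")
def truth_camera() -> CameraModel:
    return CameraModel(
        focal_x=500.0,
        focal_y=500.0,
        principal_x=319.5,
        principal_y=239.5,
        distortion=[-0.2, 0.0, 0.0, 0.0, 0.0],
        rms_reprojection_error=0.0,
        image_size=(640, 480),
    )


@pytest.fixture(scope="session")
def board_views(truth_camera):
    images, corners = generate_checkerboard_views(truth_camera, n_views=20, seed=2)
    return {"images": images, "corners": corners, "camera": truth_camera}


@pytest.fixture(scope="session")
def texture_default(scene25):
    return scene25.texture


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def flat_texture():
    """Texture with zero vessel density (background only)."""
    return generate_texture(4, (512, 512), vessel_density=0.0)
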