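import numpy as np
import pytest

from cystomap import transforms as tf
from cystomap.mapper import Frame
from cystomap.revisit import (
    LocalizationError,
    RevisitLocalization,
    build_map_features,
    localize_first_frame,
    matched_fraction,
    render_overlay,
    track_revisit,
)
from cystomap.synthetic import (
    RenderParams,
    SyntheticScene,
    generate_texture,
    render_frames,
)

from helpers import expected_canvas_pose, frame_center, pose_errors

FRAME = (200, 200)


@pytest.fixture(scope="module")
def map_features(map25):
    return build_map_features(map25)


def _expected_revisit_pose(map25, scene25, revisit_pose):
    rel = tf.compose(tf.invert(scene25.truth_poses[0]), revisit_pose)
    return tf.compose(map25.offset, rel)


class TestLocalizeFirstFrame:
    def test_exact_canvas_crop_recovers_pose(self, map25, map_features):
        # crop oracle: a window cut straight from the canvas must localize
        # at exactly its cut position
        y0, x0 = 40, 120
        crop = map25.canvas[y0 : y0 + 200, x0 : x0 + 200].copy()
        loc = localize_first_frame(
            map25, Frame(0, crop), map_features=map_features
        )
        expected = tf.translation(x0, y0)
        dt, dr, _ = pose_errors(loc.pose, expected, FRAME)
        assert loc.status == "matched_to_map"
        assert dt < 1.0 and dr < 0.5

    def test_rotated_frame_recovers_rotation(self, scene25, map25, map_features, revisit_case):
        base_pose = revisit_case["poses"][0]
        c = tf.apply_transform(base_pose, frame_center(FRAME))[0]
        rot_about_center = tf.compose(
            tf.translation(*c),
            tf.compose(
                tf.similarity_from_params(0, 0, np.radians(30), 1.0),
                tf.translation(-c[0], -c[1]),
            ),
        )
        rotated_pose = tf.compose(rot_about_center, base_pose)
        scene = SyntheticScene(
            scene25.texture, 5, 60, rotated_pose[None], RenderParams(FRAME)
        )
        frame = render_frames(scene)[0]
        base = localize_first_frame(
            map25, revisit_case["frames"][0], map_features=map_features
        )
        rotated = localize_first_frame(map25, frame, map_features=map_features)
        delta = (rotated.rotation_deg - base.rotation_deg + 180) % 360 - 180
        assert delta == pytest.approx(30.0, abs=1.0)

    def test_unrelated_texture_fails(self, map25, map_features):
        other = generate_texture(777, (512, 512), 60.0)
        frame = Frame(0, other[100:300, 100:300])
        with pytest.raises(LocalizationError) as exc_info:
            localize_first_frame(map25, frame, map_features=map_features)
        assert exc_info.value.n_features >= 0  # diagnostics attached

    def test_empty_map_raises(self, frames25):
        from cystomap.mapper import BladderMap, MapPose

        empty = BladderMap(
            canvas=np.zeros((50, 50), dtype=np.uint8),
            canvas_mask=np.zeros((50, 50), dtype=bool),
            poses=[MapPose(0, tf.identity(), "initial")],
        )
        with pytest.raises(ValueError):
            localize_first_frame(empty, frames25[0])


class TestTrackRevisit:
    def test_new_sweep_localizes_accurately(self, scene25, map25, revisit_case, map_features):
        locs = track_revisit(map25, revisit_case["frames"], map_features=map_features)
        assert matched_fraction(locs) >= 0.95
        c = frame_center(FRAME)
        for loc, truth_pose in zip(locs, revisit_case["poses"]):
            if loc.status != "matched_to_map":
                continue
            expected = _expected_revisit_pose(map25, scene25, truth_pose)
            err = np.linalg.norm(
                tf.apply_transform(expected, c) - tf.apply_transform(loc.pose, c)
            )
            assert err < 3.0

    def test_matched_error_does_not_grow_with_time(self, scene25, map25, revisit_case, map_features):
        locs = track_revisit(map25, revisit_case["frames"], map_features=map_features)
        c = frame_center(FRAME)
        errs = [
            np.linalg.norm(
                tf.apply_transform(
                    _expected_revisit_pose(map25, scene25, tp), c
                )
                - tf.apply_transform(lo.pose, c)
            )
            for lo, tp in zip(locs, revisit_case["poses"])
            if lo.status == "matched_to_map"
        ]
        half = len(errs) // 2
        assert np.mean(errs[half:]) < np.mean(errs[:half]) + 1.0

    def test_self_revisit_reproduces_map_poses(self, frames25, map25, map_features):
        locs = track_revisit(map25, frames25, map_features=map_features)
        for loc, pose in zip(locs, map25.poses):
            if loc.status != "matched_to_map":
                continue
            dt, dr, _ = pose_errors(loc.pose, pose.matrix, FRAME)
            assert dt < 1.0 and dr < 0.5

    def test_single_frame_equals_first_frame_localization(self, map25, revisit_case, map_features):
        frame = revisit_case["frames"][0]
        alone = track_revisit(map25, [frame], map_features=map_features)
        direct = localize_first_frame(map25, frame, map_features=map_features)
        assert len(alone) == 1
        np.testing.assert_array_equal(alone[0].pose, direct.pose)
        assert alone[0].status == direct.status == "matched_to_map"

    def test_gray_frames_tracked_and_fraction_exact(self, map25, revisit_case, map_features):
        frames = list(revisit_case["frames"])
        gray = np.full(FRAME, 128, dtype=np.uint8)
        frames[5] = Frame(frames[5].index, gray)
        frames[6] = Frame(frames[6].index, gray.copy())
        locs = track_revisit(map25, frames, map_features=map_features)
        n = len(frames)
        assert locs[5].status == "tracked_from_previous"
        assert locs[6].status == "tracked_from_previous"
        assert matched_fraction(locs) == (n - 2) / n

    def test_first_frame_failure_aborts(self, map25, map_features):
        frames = [Frame(0, np.full(FRAME, 128, dtype=np.uint8))]
        with pytest.raises(LocalizationError):
            track_revisit(map25, frames, map_features=map_features)

    def test_empty_sequence_raises(self, map25):
        with pytest.raises(ValueError):
            track_revisit(map25, [])

    def test_rotation_in_range(self, map25, revisit_case, map_features):
        locs = track_revisit(map25, revisit_case["frames"], map_features=map_features)
        for lo in locs:
            assert -180.0 < lo.rotation_deg <= 180.0


class TestRenderOverlay:
    def _loc(self, x, y, rotation=0.0):
        return RevisitLocalization(
            frame_index=0,
            pose=tf.translation(x - 99.5, y - 99.5),
            status="matched_to_map",
            rotation_deg=rotation,
        )

    def test_single_localization_draws_dot_and_arrow(self, map25):
        h, w = map25.shape
        loc = self._loc(w // 2, h // 2)
        img = render_overlay(map25, [loc], frame_shape=FRAME)
        assert img.shape == (h, w, 3)
        cy, cx = h // 2, w // 2
        green = (0, 200, 0)
        assert tuple(img[cy, cx]) == green
        blue_pixels = np.all(img == (0, 80, 255), axis=-1).sum()
        assert blue_pixels > 0  # the orientation arrow
        red_pixels = np.all(img == (255, 0, 0), axis=-1).sum()
        assert red_pixels == 0  # a single dot has no path polyline

    def test_two_localizations_draw_polyline(self, map25):
        h, w = map25.shape
        locs = [self._loc(w // 4, h // 2), self._loc(3 * w // 4, h // 2)]
        img = render_overlay(map25, locs, frame_shape=FRAME)
        red_pixels = np.all(img == (255, 0, 0), axis=-1).sum()
        assert red_pixels >= w // 4  # segment connecting the two dots

    def test_rotation_90_draws_perpendicular_arrow(self, map25):
        h, w = map25.shape
        img0 = render_overlay(
            map25, [self._loc(w // 2, h // 2, 0.0)], frame_shape=FRAME
        )
        img90 = render_overlay(
            map25, [self._loc(w // 2, h // 2, 90.0)], frame_shape=FRAME
        )
        blue = (0, 80, 255)

        def arrow_direction(img):
            ys, xs = np.where(np.all(img == blue, axis=-1))
            c = np.array([w // 2, h // 2])
            v = np.array([xs.mean(), ys.mean()]) - c
            return v / np.linalg.norm(v)

        d0, d90 = arrow_direction(img0), arrow_direction(img90)
        assert abs(np.dot(d0, d90)) < 0.35  # roughly perpendicular

    def test_all_failed_raises(self, map25):
        failed = RevisitLocalization(0, None, "failed", 0.0)
        with pytest.raises(ValueError):
            render_overlay(map25, [failed], frame_shape=FRAME)
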