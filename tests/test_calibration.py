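import numpy as np
import pytest

from cystomap.calibration import (
    BoardNotFound,
    CalibrationError,
    CameraModel,
    CheckerboardDetection,
    board_object_points,
    calibrate_camera,
    detect_checkerboard,
    distort_normalized,
    project_points,
    undistort,
    undistort_mask,
    undistort_normalized,
)
from cystomap.synthetic import generate_checkerboard_views

PATTERN = (5, 7)


def _corner_error_mod_symmetry(detected, truth):
    """Min corner distance over the four valid grid orderings."""
    c = detected.reshape(7, 5, 2)
    t = truth.reshape(7, 5, 2)
    variants = (t, t[::-1, ::-1], t[::-1, :], t[:, ::-1])
    return min(np.abs(c - v).max() for v in variants)


@pytest.fixture(scope="module")
def detections(board_views):
    dets = []
    for i, img in enumerate(board_views["images"]):
        det = detect_checkerboard(img, PATTERN, 10.0, view_id=i)
        assert not isinstance(det, BoardNotFound), f"view {i}: {det.reason}"
        dets.append(det)
    return dets


class TestDetectCheckerboard:
    def test_frontoparallel_board_subpixel_accuracy(self, truth_camera):
        from cystomap.synthetic import _render_board

        model = CameraModel(500.0, 500.0, 319.5, 239.5, np.zeros(5), 0.0, (640, 480))
        rotvec, tvec = np.zeros(3), np.array([-20.0, -30.0, 160.0])
        img = _render_board(model, rotvec, tvec, PATTERN, 10.0)
        obj = np.column_stack([board_object_points(PATTERN, 10.0), np.zeros(35)])
        truth = project_points(obj, rotvec, tvec, model=model)
        det = detect_checkerboard(img, PATTERN, 10.0)
        assert isinstance(det, CheckerboardDetection)
        assert len(det.corners) == 35
        assert _corner_error_mod_symmetry(det.corners, truth) < 0.5

    def test_rotated_board_ordering_consistent(self, truth_camera):
        from cystomap.synthetic import _render_board

        model = CameraModel(500.0, 500.0, 319.5, 239.5, np.zeros(5), 0.0, (640, 480))
        rotvec = np.array([0.0, 0.0, np.radians(30)])
        tvec = np.array([-15.0, -25.0, 160.0])
        img = _render_board(model, rotvec, tvec, PATTERN, 10.0)
        obj = np.column_stack([board_object_points(PATTERN, 10.0), np.zeros(35)])
        truth = project_points(obj, rotvec, tvec, model=model)
        det = detect_checkerboard(img, PATTERN, 10.0)
        assert isinstance(det, CheckerboardDetection)
        assert len(det.corners) == 35
        assert _corner_error_mod_symmetry(det.corners, truth) < 0.5

    def test_all_synthetic_views_found(self, detections, board_views):
        assert len(detections) == 20
        for det, truth in zip(detections, board_views["corners"]):
            assert _corner_error_mod_symmetry(det.corners, truth) < 0.5

    def test_uniform_image_not_found(self):
        gray = np.full((240, 320), 128, dtype=np.uint8)
        result = detect_checkerboard(gray, PATTERN)
        assert isinstance(result, BoardNotFound)
        assert not result

    def test_degenerate_image_raises(self):
        with pytest.raises(ValueError):
            detect_checkerboard(np.zeros((4, 4), dtype=np.uint8), PATTERN)

    def test_corners_within_bounds(self, detections, board_views):
        h, w = board_views["images"][0].shape
        for det in detections:
            assert (det.corners[:, 0] >= -1).all() and (det.corners[:, 0] <= w).all()
            assert (det.corners[:, 1] >= -1).all() and (det.corners[:, 1] <= h).all()


class TestCalibrateCamera:
    def test_recovers_focal_and_distortion(self, detections, board_views):
        truth = board_views["camera"]
        model = calibrate_camera(detections, 10.0, truth.image_size)
        assert model.focal_x == pytest.approx(truth.focal_x, rel=0.02)
        assert model.focal_y == pytest.approx(truth.focal_y, rel=0.02)
        assert model.distortion[0] == pytest.approx(-0.2, rel=0.10)
        assert model.rms_reprojection_error < 0.5

    def test_zero_distortion_views(self, truth_camera):
        model0 = CameraModel(500.0, 500.0, 319.5, 239.5, np.zeros(5), 0.0, (640, 480))
        _, corner_sets = generate_checkerboard_views(model0, n_views=20, seed=7)
        dets = [
            CheckerboardDetection(i, c, PATTERN, 10.0)
            for i, c in enumerate(corner_sets)
        ]
        model = calibrate_camera(dets, 10.0, (640, 480))
        assert model.focal_x == pytest.approx(500.0, rel=0.02)
        assert model.focal_y == pytest.approx(500.0, rel=0.02)
        assert np.abs(model.distortion).max() < 1e-2
        # noise-free detections: essentially exact reprojection
        assert model.rms_reprojection_error < 0.1

    def test_too_few_views_raises(self, detections):
        with pytest.raises(ValueError):
            calibrate_camera(detections[:2], 10.0, (640, 480))

    def test_identical_poses_degenerate(self, board_views):
        det = detect_checkerboard(board_views["images"][0], PATTERN, 10.0)
        with pytest.raises(CalibrationError):
            calibrate_camera([det, det, det], 10.0, (640, 480))

    def test_model_serialization_roundtrip(self, tmp_path, truth_camera):
        path = tmp_path / "camera.json"
        truth_camera.save(path)
        loaded = CameraModel.load(path)
        assert loaded.focal_x == truth_camera.focal_x
        np.testing.assert_array_equal(loaded.distortion, truth_camera.distortion)
        assert loaded.image_size == truth_camera.image_size


class TestCameraModelValidation:
    def test_negative_focal_rejected(self):
        with pytest.raises(ValueError):
            CameraModel(-1.0, 500.0, 320.0, 240.0, np.zeros(5), 0.0, (640, 480))

    def test_principal_point_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            CameraModel(500.0, 500.0, 700.0, 240.0, np.zeros(5), 0.0, (640, 480))

    def test_negative_rms_rejected(self):
        with pytest.raises(ValueError):
            CameraModel(500.0, 500.0, 320.0, 240.0, np.zeros(5), -0.1, (640, 480))


class TestDistortionModel:
    def test_undistort_normalized_inverts_distort(self):
        dist = np.array([-0.2, 0.05, 0.001, -0.002, 0.0])
        rng = np.random.default_rng(0)
        pts = rng.uniform(-0.4, 0.4, (50, 2))
        roundtrip = undistort_normalized(distort_normalized(pts, dist), dist)
        np.testing.assert_allclose(roundtrip, pts, atol=1e-8)

    def test_zero_distortion_is_identity(self):
        pts = np.array([[0.1, -0.2], [0.3, 0.4]])
        np.testing.assert_array_equal(distort_normalized(pts, np.zeros(5)), pts)


class TestUndistort:
    def test_zero_distortion_identity(self, board_views):
        model = CameraModel(500.0, 500.0, 319.5, 239.5, np.zeros(5), 0.0, (640, 480))
        img = board_views["images"][0]
        np.testing.assert_array_equal(undistort(img, model), img)

    def test_size_mismatch_raises(self, truth_camera):
        with pytest.raises(ValueError):
            undistort(np.zeros((100, 100), dtype=np.uint8), truth_camera)

    def test_deterministic(self, board_views):
        model = board_views["camera"]
        img = board_views["images"][0]
        assert undistort(img, model).tobytes() == undistort(img, model).tobytes()

    @staticmethod
    def _max_row_residual(corners):
        worst = 0.0
        grid = corners.reshape(7, 5, 2)
        for row in grid:
            centered = row - row.mean(axis=0)
            *_, s = np.linalg.svd(centered, compute_uv=False)
            worst = max(worst, s)
        return worst

    def test_straightens_board_rows(self, board_views):
        """Line-fit residual oracle: re-detected corners on the undistorted
        image must be closer to collinear than on the distorted one."""
        model = board_views["camera"]
        img = board_views["images"][0]
        det_before = detect_checkerboard(img, PATTERN, 10.0)
        det_after = detect_checkerboard(undistort(img, model), PATTERN, 10.0)
        assert isinstance(det_after, CheckerboardDetection)
        before = self._max_row_residual(det_before.corners)
        after = self._max_row_residual(det_after.corners)
        assert after < before
        assert after < 0.5

    def test_undistorted_corners_near_pinhole_projection(self, board_views):
        """After undistortion, corners should sit near the ideal (pinhole,
        no-distortion) projections of the same board pose."""
        model = board_views["camera"]
        img = board_views["images"][0]
        det = detect_checkerboard(undistort(img, model), PATTERN, 10.0)
        # ideal positions: undistort the truth corner projections
        truth = board_views["corners"][0]
        norm = np.column_stack(
            [
                (truth[:, 0] - model.principal_x) / model.focal_x,
                (truth[:, 1] - model.principal_y) / model.focal_y,
            ]
        )
        und = undistort_normalized(norm, model.distortion)
        ideal = np.column_stack(
            [
                und[:, 0] * model.focal_x + model.principal_x,
                und[:, 1] * model.focal_y + model.principal_y,
            ]
        )
        err = _corner_error_mod_symmetry(det.corners, ideal)
        assert err < 0.5

    def test_mask_excludes_out_of_source_pixels(self):
        # pincushion distortion pushes corner sources outside the image
        model = CameraModel(
            500.0, 500.0, 319.5, 239.5, [0.2, 0, 0, 0, 0], 0.0, (640, 480)
        )
        mask = undistort_mask(model)
        assert not mask[0, 0]
        assert mask[240, 320]

    def test_barrel_mask_fully_valid(self, board_views):
        # barrel distortion only pulls sources inward: every pixel valid
        assert undistort_mask(board_views["camera"]).all()
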