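"""PnP extrinsic calibration: recovery accuracy, RMSE, full pipeline."""

import numpy as np
import pytest

from tofusion.camera import CameraModel, Pose, project_points
from tofusion.errors import (
    CalibrationFailedError,
    InsufficientCorrespondencesError,
)
from tofusion.extrinsics import (
    calibrate_pair,
    load_calibration,
    reprojection_rmse,
    save_calibration,
    solve_pnp,
)
from tofusion.synthetic import (
    calibration_correspondences,
    make_target_pose,
)
from tofusion.targets import CorrespondenceSet, GridSpec


def simple_cam(**kw):
    d = dict(fx=500.0, fy=500.0, u0=320.0, v0=240.0, width=640, height=480)
    d.update(kw)
    return CameraModel(**d)


def noncoplanar_points(n=40, seed=0):
    rng = np.random.default_rng(seed)
    pts = rng.uniform([-0.15, -0.1, 0.35], [0.15, 0.1, 0.8], size=(n, 3))
    return pts


class TestSolvePnp:
    def test_identity_recovery(self):
        cam = simple_cam()
        pts = noncoplanar_points()
        uv = project_points(pts, Pose.identity(), cam)
        pose = solve_pnp(CorrespondenceSet(pts, uv), cam)
        assert np.all(np.abs(pose.rvec) < 1e-6)
        assert np.all(np.abs(pose.tvec) < 1e-6)

    def test_planar_grid_exact_recovery(self, rig, grid_spec):
        """120 coplanar grid points, zero noise: pose back to 1e-6."""
        tp = make_target_pose(grid_spec, 0.45, rvec=(0.1, 0.2, 0.3))
        corr = calibration_correspondences(rig, grid_spec, tp, "thermal")
        pose = solve_pnp(corr, rig.thermal)
        assert np.all(np.abs(pose.rvec - rig.pose_thermal.rvec) < 1e-6)
        assert np.all(np.abs(pose.tvec - rig.pose_thermal.tvec) < 1e-6)

    def test_noncoplanar_with_distortion(self):
        cam = simple_cam(k1=-0.2, k2=0.03, p1=0.001, p2=-0.001)
        true = Pose(np.array([0.1, -0.15, 0.05]), np.array([0.02, -0.01, 0.05]))
        pts = noncoplanar_points(seed=4)
        uv = project_points(pts, true, cam)
        pose = solve_pnp(CorrespondenceSet(pts, uv), cam)
        assert np.all(np.abs(pose.rvec - true.rvec) < 1e-6)
        assert np.all(np.abs(pose.tvec - true.tvec) < 1e-6)

    def test_noise_gives_bounded_rmse(self, rig, grid_spec):
        """sigma=0.5 px pixel noise: pooled RMSE in [0.2, 1.0] over 20 seeds."""
        tp = make_target_pose(grid_spec, 0.45, rvec=(0.05, -0.08, 0.02))
        rmses = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            corr = calibration_correspondences(
                rig, grid_spec, tp, "thermal", noise_sigma=0.5, rng=rng
            )
            pose = solve_pnp(corr, rig.thermal)
            rmses.append(reprojection_rmse(corr, pose, rig.thermal))
        assert 0.2 <= np.mean(rmses) <= 1.0

    def test_too_few_pairs_rejected(self):
        cam = simple_cam()
        pts = noncoplanar_points(5)
        uv = project_points(pts, Pose.identity(), cam)
        with pytest.raises(InsufficientCorrespondencesError):
            solve_pnp(CorrespondenceSet(pts, uv), cam)

    def test_deterministic(self, rig, grid_spec):
        tp = make_target_pose(grid_spec, 0.5, rvec=(0.0, 0.1, 0.0))
        rng = np.random.default_rng(9)
        corr = calibration_correspondences(
            rig, grid_spec, tp, "rgb", noise_sigma=0.3, rng=rng
        )
        p1 = solve_pnp(corr, rig.rgb)
        p2 = solve_pnp(corr, rig.rgb)
        assert np.array_equal(p1.rvec, p2.rvec)
        assert np.array_equal(p1.tvec, p2.tvec)

    def test_recovery_over_random_poses(self, rig, grid_spec):
        """Noise-free recovery < 1e-5 rad / 1e-5 m across 50 random scenes."""
        rng = np.random.default_rng(20)
        ok = 0
        for _ in range(50):
            rv = rng.uniform(-0.6, 0.6, 3)
            rv *= min(1.0, 0.6 / max(np.linalg.norm(rv), 1e-9))
            tp = make_target_pose(
                grid_spec, distance=rng.uniform(0.3, 1.0), rvec=rv
            )
            corr = calibration_correspondences(rig, grid_spec, tp, "thermal")
            pose = solve_pnp(corr, rig.thermal)
            if (
                np.max(np.abs(pose.rvec - rig.pose_thermal.rvec)) < 1e-5
                and np.max(np.abs(pose.tvec - rig.pose_thermal.tvec)) < 1e-5
            ):
                ok += 1
        assert ok == 50

    def test_local_minimum_of_rmse(self, rig, grid_spec):
        """Perturbing the solved pose never lowers the noise-free RMSE."""
        tp = make_target_pose(grid_spec, 0.45, rvec=(0.1, 0.0, -0.05))
        corr = calibration_correspondences(rig, grid_spec, tp, "thermal")
        pose = solve_pnp(corr, rig.thermal)
        base = reprojection_rmse(corr, pose, rig.thermal)
        rng = np.random.default_rng(0)
        for _ in range(10):
            d = rng.normal(0, 1e-3, 6)
            perturbed = Pose(pose.rvec + d[:3], pose.tvec + d[3:])
            assert reprojection_rmse(corr, perturbed, rig.thermal) >= base


class TestReprojectionRmse:
    def test_exact_pose_zero(self):
        cam = simple_cam()
        pts = noncoplanar_points()
        pose = Pose(np.array([0.05, 0.1, 0.0]), np.array([0.01, 0.0, 0.1]))
        uv = project_points(pts, pose, cam)
        assert reprojection_rmse(CorrespondenceSet(pts, uv), pose, cam) == 0.0

    def test_single_offset_closed_form(self):
        """One point offset by (3,4) px among n exact -> RMSE 5/sqrt(n)."""
        cam = simple_cam()
        pts = noncoplanar_points(25)
        pose = Pose.identity()
        uv = project_points(pts, pose, cam)
        uv[7] += [3.0, 4.0]
        rmse = reprojection_rmse(CorrespondenceSet(pts, uv), pose, cam)
        assert rmse == pytest.approx(5.0 / np.sqrt(25), abs=1e-12)

    def test_matches_elementwise_oracle(self):
        cam = simple_cam()
        pts = noncoplanar_points(30, seed=8)
        pose = Pose(np.array([0.02, -0.03, 0.01]), np.array([0.0, 0.01, 0.02]))
        rng = np.random.default_rng(5)
        uv = project_points(pts, pose, cam) + rng.normal(0, 1.0, (30, 2))
        expected = np.sqrt(
            np.mean(
                [
                    np.sum((project_points(p[None], pose, cam)[0] - q) ** 2)
                    for p, q in zip(pts, uv)
                ]
            )
        )
        got = reprojection_rmse(CorrespondenceSet(pts, uv), pose, cam)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_zero_residual_points_never_raise_rmse(self):
        cam = simple_cam()
        pose = Pose.identity()
        pts = noncoplanar_points(20)
        uv = project_points(pts, pose, cam)
        uv[0] += [1.0, 0.0]
        base = reprojection_rmse(CorrespondenceSet(pts, uv), pose, cam)
        extra = noncoplanar_points(10, seed=99)
        uv2 = np.vstack([uv, project_points(extra, pose, cam)])
        grown = reprojection_rmse(
            CorrespondenceSet(np.vstack([pts, extra]), uv2), pose, cam
        )
        assert grown <= base


class TestCalibratePair:
    def test_single_frame_pair(self, rig, grid_spec, calib_scene):
        res = calibrate_pair(
            [calib_scene.images["tof_mono"]],
            [calib_scene.images["thermal"]],
            calib_scene.cloud,
            grid_spec,
            rig.thermal,
            modality="thermal",
        )
        assert res.n_used == grid_spec.count
        # cloud-lookup quantization bounds accuracy to the mm level
        assert np.max(np.abs(res.pose.tvec - rig.pose_thermal.tvec)) < 0.01
        assert np.max(np.abs(res.pose.rvec - rig.pose_thermal.rvec)) < 0.03
        assert res.rmse < 2.0

    @pytest.mark.parametrize("n_corr", [26, 15])
    def test_small_curated_sets_accepted(self, rig, grid_spec, n_corr):
        """The hand-curated set sizes used in practice (26 RGB, 15 thermal)."""
        tp = make_target_pose(grid_spec, 0.5)
        corr = calibration_correspondences(rig, grid_spec, tp, "thermal")
        rng = np.random.default_rng(n_corr)
        keep = rng.choice(len(corr), size=n_corr, replace=False)
        sub = CorrespondenceSet(
            corr.object_points[keep], corr.image_points[keep], "thermal"
        )
        pose = solve_pnp(sub, rig.thermal)
        assert np.max(np.abs(pose.tvec - rig.pose_thermal.tvec)) < 1e-5

    def test_no_usable_frame_fails(self, rig, grid_spec, calib_scene):
        blank = np.full_like(calib_scene.images["tof_mono"], 128)
        with pytest.raises(CalibrationFailedError):
            calibrate_pair(
                [blank], [blank], calib_scene.cloud, grid_spec, rig.thermal
            )

    def test_yaml_round_trip(self, tmp_path, rig, grid_spec):
        tp = make_target_pose(grid_spec, 0.45)
        corr = calibration_correspondences(rig, grid_spec, tp, "rgb")
        pose = solve_pnp(corr, rig.rgb)
        from tofusion.extrinsics import CalibrationResult

        res = CalibrationResult(pose=pose, rmse=0.123, n_used=120, modality="rgb")
        path = tmp_path / "pose.yaml"
        save_calibration(res, path)
        loaded = load_calibration(path)
        assert loaded.modality == "rgb"
        assert loaded.n_used == 120
        assert np.allclose(loaded.pose.rvec, pose.rvec)
        assert np.allclose(loaded.pose.tvec, pose.tvec)
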