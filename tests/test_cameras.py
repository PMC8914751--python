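import numpy as np
import pytest

from mlgait import cameras as cm
from mlgait.errors import (
    BehindCameraError,
    ConfigError,
    DegenerateGeometryError,
    InsufficientViewsError,
)
from mlgait.trajectory_io import KeypointSeries2D

from conftest import random_camera


class TestCameraModel:
    def test_rejects_nonorthonormal_rotation(self):
        K = np.array([[100.0, 0, 50], [0, 100.0, 50], [0, 0, 1]])
        R = np.eye(3) * 1.01
        with pytest.raises(ConfigError):
            cm.CameraModel("bad", K, R, np.zeros(3))

    def test_rejects_negative_focal(self):
        K = np.array([[-100.0, 0, 50], [0, 100.0, 50], [0, 0, 1]])
        with pytest.raises(ConfigError):
            cm.CameraModel("bad", K, np.eye(3), np.zeros(3))

    def test_center(self, identity_camera):
        assert np.allclose(identity_camera.center, 0.0)


class TestProject:
    def test_optical_axis_maps_to_principal_point(self, identity_camera):
        assert cm.project(identity_camera, (0.0, 0.0, 2.0)) == (50.0, 50.0)

    def test_off_axis_point(self, identity_camera):
        # u = fx * x/z + cx = 100 * 0.5 + 50
        assert cm.project(identity_camera, (1.0, 0.0, 2.0)) == (100.0, 50.0)

    def test_behind_camera_raises(self, identity_camera):
        with pytest.raises(BehindCameraError):
            cm.project(identity_camera, (0.0, 0.0, -1.0))

    def test_undistort_backproject_roundtrip(self):
        # ray through the undistorted pixel must pass within 1e-9 m of the point
        rng = np.random.default_rng(7)
        for _ in range(20):
            cam = random_camera(rng)
            point = rng.uniform(-0.4, 0.4, 3)
            pix = np.array(cm.project(cam, point))
            xn = cm.pixel_to_normalized(cam, pix)
            ray = cam.rotation.T @ np.array([xn[0], xn[1], 1.0])
            ray /= np.linalg.norm(ray)
            rel = point - cam.center
            dist = np.linalg.norm(rel - (rel @ ray) * ray)
            assert dist < 1e-9


class TestReprojectionError:
    def test_zero_for_exact_observation(self, identity_camera):
        obs = cm.Observation2D("ident", cm.project(identity_camera, (0.1, 0.2, 2.0)))
        assert cm.reprojection_error(identity_camera, (0.1, 0.2, 2.0), obs) == 0.0

    def test_three_four_five(self, identity_camera):
        u, v = cm.project(identity_camera, (0.1, 0.2, 2.0))
        obs = cm.Observation2D("ident", (u + 3.0, v + 4.0))
        assert cm.reprojection_error(identity_camera, (0.1, 0.2, 2.0), obs) == pytest.approx(5.0)

    def test_matches_compositional_recomputation(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            cam = random_camera(rng)
            point = rng.uniform(-0.4, 0.4, 3)
            obs_px = rng.uniform(0, 1000, 2)
            obs = cm.Observation2D(cam.camera_id, tuple(obs_px))
            expected = float(np.linalg.norm(np.array(cm.project(cam, point)) - obs_px))
            assert cm.reprojection_error(cam, point, obs) == pytest.approx(expected)


class TestTriangulate:
    def _exact_setup(self, rng, point, n=3, with_distortion=True):
        cams, obs = {}, []
        while len(cams) < n:
            cam = random_camera(rng, with_distortion)
            cams[cam.camera_id] = cam
            obs.append(cm.Observation2D(cam.camera_id, cm.project(cam, point), 1.0))
        return cams, obs

    def test_exact_recovery(self):
        rng = np.random.default_rng(11)
        point = np.array([0.3, 1.1, 2.0])
        cams, obs = self._exact_setup(rng, point)
        result = cm.triangulate(obs, cams)
        assert np.linalg.norm(result.point - point) < 1e-9
        assert result.rms_reprojection_error < 1e-7
        assert result.reliable

    def test_refined_beats_dlt_under_noise(self):
        rng = np.random.default_rng(5)
        wins = 0
        for _ in range(100):
            point = rng.uniform(-0.5, 0.5, 3)
            cams, obs = self._exact_setup(rng, point)
            noisy = [cm.Observation2D(o.camera_id,
                                      (o.pixel[0] + rng.normal(0, 0.5),
                                       o.pixel[1] + rng.normal(0, 0.5)), 1.0)
                     for o in obs]
            refined = cm.triangulate(noisy, cams, refine=True)
            linear = cm.triangulate(noisy, cams, refine=False)
            wins += refined.rms_reprojection_error <= linear.rms_reprojection_error + 1e-12
        assert wins >= 95

    def test_single_view_raises(self, identity_camera):
        obs = [cm.Observation2D("ident", (50.0, 50.0)),
               cm.Observation2D("ident", (51.0, 50.0))]
        with pytest.raises(InsufficientViewsError):
            cm.triangulate(obs, {"ident": identity_camera})

    def test_identical_camera_poses_degenerate(self, identity_camera):
        clone = cm.CameraModel("clone", identity_camera.intrinsics,
                               identity_camera.rotation, identity_camera.translation,
                               image_size=identity_camera.image_size)
        cams = {"ident": identity_camera, "clone": clone}
        obs = [cm.Observation2D("ident", (55.0, 50.0)),
               cm.Observation2D("clone", (55.0, 50.0))]
        with pytest.raises(DegenerateGeometryError):
            cm.triangulate(obs, cams)

    def test_noise_monotonicity(self, rig, camera_map):
        rng = np.random.default_rng(17)
        points = rng.uniform(0, 1, (200, 3)) * np.array([6.0, 1.8, 0.8])
        medians = []
        for sigma in (0.0, 0.5, 1.0, 2.0):
            errs = []
            for p in points:
                obs = [cm.Observation2D(c.camera_id,
                                        tuple(np.array(cm.project(c, p))
                                              + rng.normal(0, sigma, 2)), 1.0)
                       for c in rig]
                res = cm.triangulate(obs, camera_map)
                errs.append(np.linalg.norm(res.point - p))
            medians.append(np.median(errs))
        assert all(a <= b + 1e-12 for a, b in zip(medians, medians[1:]))

    def test_confidence_downweighting_helps(self, rig, camera_map):
        rng = np.random.default_rng(23)
        err_w, err_eq = [], []
        for _ in range(120):
            p = rng.uniform(0, 1, 3) * np.array([6.0, 1.8, 0.8])
            pix = [np.array(cm.project(c, p)) for c in rig]
            pix[0] = pix[0] + rng.normal(0, 5.0, 2)       # corrupted view
            pix[1] = pix[1] + rng.normal(0, 0.5, 2)
            pix[2] = pix[2] + rng.normal(0, 0.5, 2)
            confs_weighted = [0.05, 1.0, 1.0]
            obs_w = [cm.Observation2D(c.camera_id, tuple(px), cw)
                     for c, px, cw in zip(rig, pix, confs_weighted)]
            obs_eq = [cm.Observation2D(c.camera_id, tuple(px), 1.0)
                      for c, px in zip(rig, pix)]
            err_w.append(np.linalg.norm(cm.triangulate(obs_w, camera_map).point - p))
            err_eq.append(np.linalg.norm(cm.triangulate(obs_eq, camera_map).point - p))
        assert np.median(err_w) <= np.median(err_eq) + 1e-12


class TestTriangulateSeries:
    def test_simulator_roundtrip(self, default_walk, rig, camera_map):
        from mlgait import synthetic_gait as sg

        series, _ = default_walk
        views = sg.render_views(series, rig, 0.0, 0.0, seed=0)
        rec = cm.triangulate_series(views, camera_map, skeleton=series.skeleton)
        assert not rec.missing.any()
        assert np.nanmax(np.linalg.norm(rec.xyz - series.xyz, axis=2)) < 1e-6

    def test_zero_confidence_view_still_reconstructed(self, default_walk, rig, camera_map):
        from mlgait import synthetic_gait as sg

        series, _ = default_walk
        views = sg.render_views(series, rig, 0.0, 0.0, seed=0)
        k = series.index("left_heel")
        views[0].data[20:30, k, 2] = 0.0
        rec = cm.triangulate_series(views, camera_map, min_confidence=0.5)
        assert not rec.missing[20:30, k].any()
        assert np.nanmax(np.linalg.norm(rec.xyz[20:30, k] - series.xyz[20:30, k],
                                        axis=1)) < 1e-6

    def test_all_views_below_confidence_marks_missing(self, default_walk, rig, camera_map):
        from mlgait import synthetic_gait as sg

        series, _ = default_walk
        views = sg.render_views(series, rig, 0.0, 0.0, seed=0)
        k = series.index("left_heel")
        for v in views:
            v.data[40, k, 2] = 0.0
        rec = cm.triangulate_series(views, camera_map, min_confidence=0.5)
        assert rec.missing[40, k]
        assert np.isnan(rec.xyz[40, k]).all()

    def test_mismatched_keypoints_raise(self, rig, camera_map):
        a = KeypointSeries2D("cam0", 30.0, ("kp1",), np.zeros((5, 1, 3)),
                             np.zeros((5, 1), bool))
        b = KeypointSeries2D("cam1", 30.0, ("kp2",), np.zeros((5, 1, 3)),
                             np.zeros((5, 1), bool))
        with pytest.raises(Exception):
            cm.triangulate_series([a, b], camera_map)


class TestCalibrationIO:
    @pytest.mark.parametrize("ext", ["json", "yaml"])
    def test_bit_exact_roundtrip(self, tmp_path, ext):
        rng = np.random.default_rng(2)
        cams = [random_camera(rng) for _ in range(3)]
        path = tmp_path / f"calib.{ext}"
        cm.write_calibration(cams, path)
        back = cm.read_calibration(path)
        assert set(back) == {c.camera_id for c in cams}
        for c in cams:
            b = back[c.camera_id]
            assert np.array_equal(b.intrinsics, c.intrinsics)
            assert np.array_equal(b.rotation, c.rotation)
            assert np.array_equal(b.translation, c.translation)
            assert np.array_equal(b.distortion, c.distortion)
            assert b.image_size == c.image_size

    def test_mm_units_converted(self, tmp_path, identity_camera):
        path = tmp_path / "calib.json"
        cm.write_calibration([identity_camera], path, units="mm")
        back = cm.read_calibration(path)
        assert np.allclose(back["ident"].translation, identity_camera.translation)
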