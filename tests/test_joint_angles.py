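import numpy as np
import pytest

from mlgait import gait_events as ge
from mlgait import gait_params as gp
from mlgait import joint_angles as ja
from mlgait import preprocess as pp
from mlgait import synthetic_gait as sg
from mlgait import trajectory_io as tio
from mlgait.errors import DataError


@pytest.fixture(scope="module")
def smooth_walk(default_walk):
    series, gt = default_walk
    smooth = pp.butterworth_lowpass(series, 12.0)
    cycles = ge.segment_cycles(series)
    direction, _ = gp.walking_direction(smooth)
    return smooth, cycles, direction, gt


def bent_leg_series(knee_angle_deg):
    """A static pose with the left knee bent by the given flexion angle,
    in the sagittal (x-y) plane."""
    sk = tio.h36m21_skeleton()
    n = 10
    xyz = np.zeros((n, 21, 3))
    hip = np.array([0.0, 1.0, 0.1])
    thigh, shank = 0.45, 0.45
    flex = np.radians(knee_angle_deg)
    knee = hip + thigh * np.array([0.0, -1.0, 0.0])
    shank_dir = np.array([np.sin(flex), -np.cos(flex), 0.0])
    ankle = knee + shank * shank_dir
    poses = {
        "pelvis": [0, 1.0, 0], "belly": [0, 1.25, 0], "neck": [0, 1.5, 0],
        "nose": [0.05, 1.6, 0], "head": [0, 1.7, 0],
        "left_hip": hip, "right_hip": [0, 1.0, -0.1],
        "left_knee": knee, "left_ankle": ankle,
        "left_heel": ankle + [-0.05, -0.05, 0], "left_toe": ankle + [0.15, -0.07, 0],
        "right_knee": [0, 0.55, -0.1], "right_ankle": [0, 0.1, -0.1],
        "right_heel": [-0.05, 0.05, -0.1], "right_toe": [0.15, 0.03, -0.1],
        "left_shoulder": [0, 1.45, 0.2], "left_elbow": [0, 1.2, 0.2],
        "left_wrist": [0, 0.95, 0.2], "right_shoulder": [0, 1.45, -0.2],
        "right_elbow": [0, 1.2, -0.2], "right_wrist": [0, 0.95, -0.2],
    }
    for name, pos in poses.items():
        xyz[:, sk.index(name)] = np.asarray(pos, float)
    return tio.KeypointSeries3D(30.0, tuple(sk.keypoints), xyz,
                                np.zeros((n, 21), bool), "Y", sk)


class TestKneeFlexionFixtures:
    @pytest.mark.parametrize("angle", [0.0, 90.0])
    def test_exact_fixture_angles(self, angle):
        series = bent_leg_series(angle)
        frames = np.arange(series.n_frames)
        hip = series.role_trajectory("left_hip")[frames]
        knee = series.role_trajectory("left_knee")[frames]
        ankle = series.role_trajectory("left_ankle")[frames]
        v1 = hip - knee
        v2 = ankle - knee
        cosang = np.einsum("ij,ij->i", v1, v2) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
        measured = 180.0 - np.degrees(np.arccos(np.clip(cosang, -1, 1)))
        assert np.max(np.abs(measured - angle)) < 1e-6


class TestPelvisFrame:
    def test_canonical_pose(self):
        series = bent_leg_series(0.0)
        forward, up, lateral = ja.pelvis_frame(series, 0, np.array([1.0, 0, 0]))
        assert lateral == pytest.approx([0, 0, 1], abs=1e-9)
        assert up == pytest.approx([0, 1, 0], abs=1e-9)
        assert forward == pytest.approx([1, 0, 0], abs=1e-9)

    def test_rotation_equivariance(self):
        series = bent_leg_series(25.0)
        theta = np.radians(71.0)
        R = np.array([[np.cos(theta), 0, np.sin(theta)],
                      [0, 1, 0],
                      [-np.sin(theta), 0, np.cos(theta)]])
        moved = tio.rotate_world(series, R)
        f0, u0, l0 = ja.pelvis_frame(series, 0)
        f1, u1, l1 = ja.pelvis_frame(moved, 0)
        assert np.allclose(R @ f0, f1, atol=1e-9)
        assert np.allclose(R @ u0, u1, atol=1e-9)
        assert np.allclose(R @ l0, l1, atol=1e-9)

    def test_simulator_frame_accuracy(self, smooth_walk):
        smooth, cycles, direction, gt = smooth_walk
        tilt = np.radians(sg.PELVIS_TILT_DEG)
        true_forward = np.array([np.cos(tilt), -np.sin(tilt), 0.0])
        mid = smooth.n_frames // 2
        forward, up, lateral = ja.pelvis_frame(smooth, mid, direction)
        angle = np.degrees(np.arccos(np.clip(np.dot(forward, true_forward), -1, 1)))
        assert angle < 2.0

    def test_coincident_hips_error(self):
        series = bent_leg_series(0.0)
        rh = series.skeleton.index("right_hip")
        lh = series.skeleton.index("left_hip")
        series.xyz[:, rh] = series.xyz[:, lh]
        with pytest.raises(DataError, match="hips"):
            ja.pelvis_frame(series, 0)


class TestComputeJointAngles:
    def test_simulator_profiles_recovered(self, smooth_walk):
        smooth, cycles, direction, gt = smooth_walk
        for cycle in cycles:
            if not cycle.is_central:
                continue
            jac = ja.compute_joint_angles(smooth, cycle, direction)
            for name in ja.ANGLE_NAMES:
                rms = np.sqrt(np.mean(
                    (jac.curves[name] - gt.angle_profiles[cycle.side][name]) ** 2))
                assert rms <= 2.0, f"{cycle.side} {name}: RMS {rms:.2f} deg"

    def test_rigid_motion_invariance(self, smooth_walk):
        smooth, cycles, direction, _ = smooth_walk
        cycle = next(c for c in cycles if c.is_central)
        base = ja.compute_joint_angles(smooth, cycle, direction)
        theta = np.radians(203.0)
        R = np.array([[np.cos(theta), 0, np.sin(theta)],
                      [0, 1, 0],
                      [-np.sin(theta), 0, np.cos(theta)]])
        moved = tio.rotate_world(smooth, R, (2.0, -0.7, 1.0))
        d_rot = R @ direction
        rotated = ja.compute_joint_angles(moved, cycle, d_rot)
        for name in ja.ANGLE_NAMES:
            assert np.max(np.abs(base.curves[name] - rotated.curves[name])) < 1e-6

    def test_cyclicity(self, smooth_walk):
        smooth, cycles, direction, _ = smooth_walk
        for cycle in cycles:
            jac = ja.compute_joint_angles(smooth, cycle, direction)
            for name in ja.ANGLE_NAMES:
                c = jac.curves[name]
                assert abs(c[0] - c[-1]) <= 3.0, f"{name}: {abs(c[0] - c[-1]):.2f}"

    def test_mirror_symmetry(self, default_walk):
        series, _ = default_walk
        sk = series.skeleton
        mirrored_xyz = series.xyz.copy()
        mirrored_xyz[..., 2] *= -1.0
        # swap left/right keypoint columns
        order = []
        for name in sk.keypoints:
            if name.startswith("left_"):
                order.append(sk.index("right_" + name[5:]))
            elif name.startswith("right_"):
                order.append(sk.index("left_" + name[6:]))
            else:
                order.append(sk.index(name))
        mirrored = series.with_xyz(mirrored_xyz[:, order, :],
                                   series.missing[:, order])

        def central_curves(s):
            smooth = pp.butterworth_lowpass(s, 12.0)
            direction, _ = gp.walking_direction(smooth)
            out = {}
            for c in ge.segment_cycles(s):
                if c.is_central:
                    out[c.side] = ja.compute_joint_angles(smooth, c, direction)
            return out

        orig = central_curves(series)
        mirr = central_curves(mirrored)
        for side, other in (("left", "right"), ("right", "left")):
            for name in ja.ANGLE_NAMES:
                assert np.max(np.abs(orig[side].curves[name]
                                     - mirr[other].curves[name])) < 0.5

    def test_missing_keypoint_errors(self, smooth_walk):
        smooth, cycles, direction, _ = smooth_walk
        cycle = next(c for c in cycles if c.is_central)
        broken = smooth.copy()
        k = broken.skeleton.index(f"{cycle.side}_knee")
        broken.missing[cycle.start_index:cycle.end_index + 1, k] = True
        with pytest.raises(DataError, match="missing"):
            ja.compute_joint_angles(broken, cycle, direction)

    def test_sanity_band(self, smooth_walk):
        smooth, cycles, direction, _ = smooth_walk
        for cycle in cycles:
            jac = ja.compute_joint_angles(smooth, cycle, direction)
            knee = jac.curves["knee_flexion"]
            assert np.all(knee >= -15.0) and np.all(knee <= 180.0)


class TestAnglesTable:
    def test_long_layout(self, smooth_walk):
        smooth, cycles, direction, _ = smooth_walk
        jac = ja.compute_joint_angles(smooth, cycles[0], direction)
        table = ja.angles_table([jac], "long")
        assert len(table) == 5 * 101
        assert set(table["angle"]) == set(ja.ANGLE_NAMES)

    def test_wide_layout(self, smooth_walk):
        smooth, cycles, direction, _ = smooth_walk
        jac = ja.compute_joint_angles(smooth, cycles[0], direction)
        table = ja.angles_table([jac], "wide")
        assert len(table) == 5
        assert "p100" in table.columns
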