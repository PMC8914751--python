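import numpy as np
import pytest

from mlgait import trajectory_io as tio
from mlgait.errors import ConfigError, DataError, MissingDataError


@pytest.fixture
def small_series_3d():
    rng = np.random.default_rng(0)
    names = ("a", "b", "c")
    xyz = rng.normal(size=(7, 3, 3))
    missing = np.zeros((7, 3), bool)
    missing[2, 1] = True
    xyz[2, 1] = np.nan
    return tio.KeypointSeries3D(30.0, names, xyz, missing)


class TestSkeletons:
    def test_h36m21_has_21_keypoints_and_all_roles(self):
        sk = tio.h36m21_skeleton()
        assert len(sk.keypoints) == 21
        for role in tio.GAIT_ROLES:
            assert sk.role_keypoint(role) in sk.keypoints

    def test_davis22_has_22_markers(self):
        sk = tio.davis22_skeleton()
        assert len(sk.keypoints) == 22
        # no heel markers in this protocol
        with pytest.raises(DataError):
            sk.role_keypoint("left_heel")

    def test_duplicate_names_rejected(self):
        with pytest.raises(ConfigError):
            tio.SkeletonDefinition("x", ("a", "a"), ("center", "center"))

    def test_bone_endpoint_must_exist(self):
        with pytest.raises(ConfigError):
            tio.SkeletonDefinition("x", ("a", "b"), ("center", "center"),
                                   bones=(("a", "z"),))

    def test_role_must_bind_existing_keypoint(self):
        with pytest.raises(ConfigError):
            tio.SkeletonDefinition("x", ("a",), ("center",),
                                   roles={"left_heel": "nope"})

    def test_unknown_skeleton_name(self):
        with pytest.raises(ConfigError):
            tio.get_skeleton("nope")


class TestCsv2D:
    def _series(self, rng):
        data = rng.normal(size=(5, 2, 3))
        data[..., 2] = rng.uniform(0, 1, size=(5, 2))
        missing = np.zeros((5, 2), bool)
        missing[3, 0] = True
        data[3, 0] = np.nan
        return tio.KeypointSeries2D("camX", 30.0, ("kp_a", "kp_b"), data, missing)

    def test_bit_exact_roundtrip(self, tmp_path):
        series = self._series(np.random.default_rng(1))
        path = tmp_path / "v.csv"
        tio.write_keypoints_2d(series, path)
        back = tio.read_keypoints_2d(path)
        assert back.camera_id == "camX"
        assert back.fps == series.fps
        assert back.n_frames == series.n_frames
        assert np.array_equal(back.missing, series.missing)
        assert np.array_equal(back.data[~back.missing], series.data[~series.missing])

    def test_missing_fps_metadata_errors(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("# camera_id=c\nframe,keypoint,u,v,confidence\n0,a,1.0,2.0,0.5\n")
        with pytest.raises(DataError, match="fps"):
            tio.read_keypoints_2d(path)

    def test_sparse_rows_mark_others_missing(self, tmp_path):
        path = tmp_path / "sparse.csv"
        path.write_text("# camera_id=c\n# fps=30\n# frames=2\n"
                        "frame,keypoint,u,v,confidence\n0,a,1.0,2.0,0.5\n")
        sk = tio.SkeletonDefinition("s3", ("a", "b", "c"),
                                    ("center", "center", "center"))
        back = tio.read_keypoints_2d(path, sk)
        assert not back.missing[0, 0]
        assert back.missing[0, 1] and back.missing[0, 2]
        assert back.missing[1].all()

    def test_unknown_keypoint_vs_skeleton(self, tmp_path):
        path = tmp_path / "u.csv"
        path.write_text("# camera_id=c\n# fps=30\nframe,keypoint,u,v,confidence\n"
                        "0,zz,1.0,2.0,0.5\n")
        with pytest.raises(DataError, match="zz"):
            tio.read_keypoints_2d(path, tio.h36m21_skeleton())

    def test_non_monotone_frames_error(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("# camera_id=c\n# fps=30\nframe,keypoint,u,v,confidence\n"
                        "1,a,1.0,2.0,0.5\n0,a,1.0,2.0,0.5\n")
        with pytest.raises(DataError, match="monoton"):
            tio.read_keypoints_2d(path)


class TestCsv3D:
    def test_bit_exact_roundtrip(self, tmp_path, small_series_3d):
        path = tmp_path / "s.csv"
        tio.write_keypoints_3d(small_series_3d, path)
        back = tio.read_keypoints_3d(path)
        assert back.fps == small_series_3d.fps
        assert np.array_equal(back.missing, small_series_3d.missing)
        assert np.array_equal(back.xyz[~back.missing],
                              small_series_3d.xyz[~small_series_3d.missing])

    def test_mm_units_divided(self, tmp_path):
        path = tmp_path / "mm.csv"
        path.write_text("# fps=30\n# units=mm\n# frames=1\n"
                        "frame,keypoint,x,y,z\n0,a,1000.0,2000.0,-500.0\n")
        back = tio.read_keypoints_3d(path)
        assert np.allclose(back.xyz[0, 0], [1.0, 2.0, -0.5])

    def test_vertical_axis_preserved(self, tmp_path, small_series_3d):
        from dataclasses import replace

        path = tmp_path / "z.csv"
        tio.write_keypoints_3d(replace(small_series_3d, vertical_axis="Z"), path)
        assert tio.read_keypoints_3d(path).vertical_axis == "Z"


class TestTrc:
    @staticmethod
    def _parse_trc(path):
        """Independent minimal TRC parser used as the round-trip oracle."""
        lines = path.read_text().splitlines()
        counts = lines[2].split("\t")
        n_frames, n_markers = int(counts[2]), int(counts[3])
        markers = [m for m in lines[3].split("\t")[2:] if m]
        data = []
        for row in lines[6:6 + n_frames]:
            fields = row.split("\t")
            data.append([float(x) for x in fields[2:2 + 3 * n_markers]])
        return markers, np.asarray(data).reshape(n_frames, n_markers, 3)

    def test_header_contract(self, tmp_path):
        series = tio.KeypointSeries3D(30.0, ("m1", "m2"),
                                      np.arange(12, dtype=float).reshape(2, 2, 3),
                                      np.zeros((2, 2), bool))
        path = tmp_path / "two.trc"
        tio.write_trc(series, path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("PathFileType\t4")
        vals = lines[2].split("\t")
        assert vals[2] == "2" and vals[3] == "2"  # NumFrames, NumMarkers
        first, second = lines[6].split("\t"), lines[7].split("\t")
        assert float(first[1]) == 0.0
        assert float(second[1]) == pytest.approx(1.0 / 30.0)

    def test_parse_back_oracle(self, tmp_path):
        rng = np.random.default_rng(4)
        xyz = rng.normal(size=(9, 4, 3))
        series = tio.KeypointSeries3D(60.0, ("a", "b", "c", "d"), xyz,
                                      np.zeros((9, 4), bool))
        path = tmp_path / "r.trc"
        tio.write_trc(series, path)
        markers, data = self._parse_trc(path)
        assert markers == ["a", "b", "c", "d"]
        assert np.max(np.abs(data - xyz)) < 1e-6

    def test_missing_samples_rejected(self, tmp_path, small_series_3d):
        with pytest.raises(MissingDataError):
            tio.write_trc(small_series_3d, tmp_path / "x.trc")


class TestAxisPermutation:
    def test_downstream_params_invariant_to_vertical_axis(self, default_walk):
        """A Z-up version of a walk yields identical gait parameters."""
        from dataclasses import replace

        from mlgait import gait_events, gait_params, preprocess

        series, _ = default_walk
        # rotate Y-up -> Z-up: (x, y, z) -> (x, -z, y)
        R = np.array([[1.0, 0, 0], [0, 0, -1.0], [0, 1.0, 0]])
        rotated = replace(tio.rotate_world(series, R), vertical_axis="Z")

        def params_of(s):
            smooth = preprocess.butterworth_lowpass(s, 12.0)
            cycles = gait_events.segment_cycles(s)
            d, l = gait_params.walking_direction(smooth)
            return [gait_params.compute_params(smooth, c, d, l) for c in cycles]

        pa, pb = params_of(series), params_of(rotated)
        assert len(pa) == len(pb) > 0
        for a, b in zip(pa, pb):
            assert a.stride_length_m == pytest.approx(b.stride_length_m, abs=1e-9)
            assert a.stance_pct == pytest.approx(b.stance_pct, abs=1e-9)
            assert a.stride_width_m == pytest.approx(b.stride_width_m, abs=1e-9)
            assert a.speed_m_s == pytest.approx(b.speed_m_s, abs=1e-9)
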