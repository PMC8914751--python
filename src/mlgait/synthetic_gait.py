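"""Kinematic gait simulator with exact ground truth.

Generates 3D keypoint trajectories of a walker with analytically known gait
events, spatio-temporal parameters, and joint-angle profiles, plus
multi-view 2D renderings through calibrated virtual cameras.  The simulation
is kinematic by design so every ground-truth quantity is exact by
construction:

* the pelvis root advances at constant mean speed with small sinusoidal
  vertical/lateral oscillation;
* each heel is anchored (exactly zero velocity) during stance and advances
  by one stride length during swing along a minimum-jerk horizontal /
  sinusoidal-clearance vertical path;
* the foot is rigid (toe and ankle ride on the heel with a prescribed
  swing-phase pitch profile);
* the knee is placed by exact two-link inverse kinematics between hip and
  ankle.

Left and right are in exact antiphase.  The world is Y-up with progression
along +X.  Stride time is snapped to the frame grid so events fall exactly
on frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from mlgait.cameras import CameraModel, project_many
from mlgait.errors import ConfigError, DataError
from mlgait.preprocess import CYCLE_SAMPLES
from mlgait.trajectory_io import (
    KeypointSeries2D,
    KeypointSeries3D,
    h36m21_skeleton,
)

PELVIS_TILT_DEG = 6.0        # constant anterior pelvic tilt of the model
HEEL_HEIGHT = 0.0            # heel keypoint height on the ground
ANKLE_OFFSET = np.array([0.04, 0.08, 0.0])   # ankle in foot frame (from heel)
TOE_HEIGHT = 0.02
SWING_CLEARANCE = 0.05       # peak heel lift during swing, meters
FOOT_PITCH_AMPLITUDE = 0.30  # radians of swing foot pitch
VERTICAL_OSC = 0.015         # pelvis vertical oscillation amplitude
LATERAL_OSC = 0.01           # pelvis lateral oscillation amplitude


@dataclass(frozen=True)
class GaitSimConfig:
    stride_time_s: float = 1.13
    stride_length_m: float = 1.35
    duty_factor: float = 0.592
    step_width_m: float = 0.10
    thigh_m: float = 0.50
    shank_m: float = 0.50
    foot_m: float = 0.20
    pelvis_height_m: float = 0.92
    fps: float = 30.0
    duration_s: float = 5.0
    trajectory_noise_sd_m: float = 0.0
    pixel_noise_sd_px: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.4 < self.duty_factor < 0.8):
            raise ConfigError("duty_factor must be in (0.4, 0.8)")
        if self.stride_length_m >= 2 * (self.thigh_m + self.shank_m):
            raise ConfigError("stride length unreachable for the leg length")
        if self.fps < 10:
            raise ConfigError("fps must be >= 10")
        for name in ("stride_time_s", "stride_length_m", "step_width_m",
                     "thigh_m", "shank_m", "foot_m", "pelvis_height_m",
                     "duration_s"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must be in [0, 1)")


@dataclass
class GaitGroundTruth:
    """Exact events, parameters, and angle profiles of a simulated walk."""

    heel_strike_frames: dict[str, list[int]]
    toe_off_frames: dict[str, list[int]]
    params: list[dict]                       # per-cycle true parameter dicts
    angle_profiles: dict[str, dict[str, np.ndarray]]  # side -> angle -> 101 samples
    clean_series: KeypointSeries3D           # noise-free trajectories
    stride_frames: int
    config: GaitSimConfig

    @property
    def stance_pct(self) -> float:
        return 100.0 * self.config.duty_factor


def _minimum_jerk(tau: np.ndarray) -> np.ndarray:
    return 10 * tau ** 3 - 15 * tau ** 4 + 6 * tau ** 5


def _heel_kinematics(t: np.ndarray, strike_times: np.ndarray, anchors: np.ndarray,
                     stance_s: float, swing_s: float, stride_length: float,
                     z_pos: float) -> np.ndarray:
    """Heel trajectory given the (extended) sequence of strike times/anchors."""
    out = np.zeros((t.size, 3))
    out[:, 2] = z_pos
    out[:, 1] = HEEL_HEIGHT
    # which cycle does each sample fall into?
    idx = np.searchsorted(strike_times, t, side="right") - 1
    idx = np.clip(idx, 0, len(strike_times) - 2)
    local = t - strike_times[idx]
    in_swing = local > stance_s
    out[:, 0] = anchors[idx]
    tau = np.clip((local[in_swing] - stance_s) / swing_s, 0.0, 1.0)
    out[in_swing, 0] += stride_length * _minimum_jerk(tau)
    out[in_swing, 1] += SWING_CLEARANCE * np.sin(np.pi * tau) ** 2
    return out


def _foot_pitch(t: np.ndarray, strike_times: np.ndarray, stance_s: float,
                swing_s: float) -> np.ndarray:
    """Foot pitch angle (rad): 0 during stance, prescribed profile in swing."""
    idx = np.searchsorted(strike_times, t, side="right") - 1
    idx = np.clip(idx, 0, len(strike_times) - 2)
    local = t - strike_times[idx]
    pitch = np.zeros_like(t)
    in_swing = local > stance_s
    tau = np.clip((local[in_swing] - stance_s) / swing_s, 0.0, 1.0)
    pitch[in_swing] = -FOOT_PITCH_AMPLITUDE * np.sin(2 * np.pi * tau)
    return pitch


def _rigid_foot_point(heel: np.ndarray, pitch: np.ndarray,
                      local: np.ndarray) -> np.ndarray:
    """Rotate a foot-local point about the heel by the pitch angle (x-y plane)."""
    c, s = np.cos(pitch), np.sin(pitch)
    x = c * local[0] - s * local[1]
    y = s * local[0] + c * local[1]
    out = np.empty((heel.shape[0], 3))
    out[:, 0] = heel[:, 0] + x
    out[:, 1] = heel[:, 1] + y
    out[:, 2] = heel[:, 2] + local[2]
    return out


def _solve_knee(hip: np.ndarray, ankle: np.ndarray, thigh: float,
                shank: float) -> np.ndarray:
    """Exact two-link IK; the knee bends toward +X (forward)."""
    diff = ankle - hip
    d = np.linalg.norm(diff, axis=1)
    if np.any(d > thigh + shank - 1e-12):
        raise DataError(
            f"IK infeasible: hip-ankle distance up to {d.max():.3f} m exceeds "
            f"thigh+shank = {thigh + shank:.3f} m")
    n = diff / d[:, None]
    a = (thigh ** 2 - shank ** 2 + d ** 2) / (2 * d)
    h = np.sqrt(np.maximum(thigh ** 2 - a ** 2, 0.0))
    fwd = np.zeros_like(n)
    fwd[:, 0] = 1.0
    b = fwd - np.einsum("ij,ij->i", fwd, n)[:, None] * n
    bn = np.linalg.norm(b, axis=1)
    bn[bn < 1e-12] = 1.0
    b = b / bn[:, None]
    return hip + a[:, None] * n + h[:, None] * b


def simulate_walk(config: GaitSimConfig) -> tuple[KeypointSeries3D, GaitGroundTruth]:
    """Simulate one straight walk; returns the (possibly noisy) series and
    the exact ground truth (with the noise-free series embedded)."""
    skeleton = h36m21_skeleton()
    fps = config.fps
    n_frames = int(round(config.duration_s * fps))
    stride_frames = int(round(config.stride_time_s * fps))
    T = stride_frames / fps                      # stride time on the frame grid
    stance_s = config.duty_factor * T
    swing_s = T - stance_s
    L = config.stride_length_m
    v = L / T
    t = np.arange(n_frames) / fps

    # strike schedules (extended one cycle beyond each end of the record)
    offset_frames = max(1, int(round(0.3 * stride_frames)))
    half = int(round(stride_frames / 2))
    first = {"left": offset_frames, "right": offset_frames + half}
    strike_frames: dict[str, np.ndarray] = {}
    for side in ("left", "right"):
        k = np.arange(first[side] - 2 * stride_frames,
                      n_frames + 2 * stride_frames, stride_frames)
        strike_frames[side] = k
    strike_times = {s: strike_frames[s] / fps for s in strike_frames}

    # pelvis root
    x0 = 0.0
    root = np.zeros((n_frames, 3))
    root[:, 0] = x0 + v * t
    root[:, 1] = (config.pelvis_height_m
                  + VERTICAL_OSC * np.sin(4 * np.pi * (t / T)))
    root[:, 2] = LATERAL_OSC * np.sin(2 * np.pi * (t / T))

    # heel anchors: at each strike the new stance position is half a
    # stance-length ahead of the pelvis
    w = config.step_width_m
    series_xyz = np.zeros((n_frames, len(skeleton.keypoints), 3))

    per_side: dict[str, dict[str, np.ndarray]] = {}
    for side, z_sign in (("left", +1.0), ("right", -1.0)):
        st = strike_times[side]
        anchors = (x0 + v * st) + L * config.duty_factor / 2.0
        z_pos = z_sign * w / 2.0
        heel = _heel_kinematics(t, st, anchors, stance_s, swing_s, L, z_pos)
        pitch = _foot_pitch(t, st, stance_s, swing_s)
        toe = _rigid_foot_point(heel, pitch, np.array([config.foot_m, TOE_HEIGHT, 0.0]))
        ankle = _rigid_foot_point(heel, pitch, ANKLE_OFFSET)
        hip = root.copy()
        hip[:, 2] += z_sign * w / 2.0
        knee = _solve_knee(hip, ankle, config.thigh_m, config.shank_m)
        per_side[side] = {"heel": heel, "toe": toe, "ankle": ankle,
                          "hip": hip, "knee": knee}

    # trunk / head: rigid offsets from the root with constant anterior tilt
    tilt = math.radians(PELVIS_TILT_DEG)
    trunk_dir = np.array([math.sin(tilt), math.cos(tilt), 0.0])
    belly = root + 0.25 * trunk_dir
    neck = root + 0.55 * trunk_dir
    head = neck + np.array([0.0, 0.18, 0.0])
    nose = neck + np.array([0.08, 0.12, 0.0])

    phase = 2 * np.pi * t / T
    for side, z_sign, ph in (("left", 1.0, 0.0), ("right", -1.0, np.pi)):
        shoulder = neck + np.array([0.0, -0.03, z_sign * 0.18])
        swingx = 0.10 * np.sin(phase + ph)
        elbow = shoulder + np.stack(
            [swingx, np.full(n_frames, -0.28), np.zeros(n_frames)], axis=1)
        wrist = shoulder + np.stack(
            [2.0 * swingx, np.full(n_frames, -0.53), np.zeros(n_frames)], axis=1)
        series_xyz[:, skeleton.index(f"{side}_shoulder")] = shoulder
        series_xyz[:, skeleton.index(f"{side}_elbow")] = elbow
        series_xyz[:, skeleton.index(f"{side}_wrist")] = wrist

    series_xyz[:, skeleton.index("pelvis")] = root
    series_xyz[:, skeleton.index("belly")] = belly
    series_xyz[:, skeleton.index("neck")] = neck
    series_xyz[:, skeleton.index("head")] = head
    series_xyz[:, skeleton.index("nose")] = nose
    for side in ("left", "right"):
        for part in ("hip", "knee", "ankle", "heel", "toe"):
            series_xyz[:, skeleton.index(f"{side}_{part}")] = per_side[side][part]

    missing = np.zeros((n_frames, len(skeleton.keypoints)), dtype=bool)
    clean = KeypointSeries3D(fps, tuple(skeleton.keypoints), series_xyz.copy(),
                             missing.copy(), "Y", skeleton)

    # ground-truth events restricted to observed, complete information
    hs: dict[str, list[int]] = {}
    to: dict[str, list[int]] = {}
    for side in ("left", "right"):
        frames = [int(k) for k in strike_frames[side] if 0 < k < n_frames]
        hs[side] = frames
        to[side] = [t for t in (int(round(k + config.duty_factor * stride_frames))
                                for k in frames) if t < n_frames]

    params: list[dict] = []
    for side in ("left", "right"):
        for s0, s1 in zip(hs[side][:-1], hs[side][1:]):
            params.append({
                "side": side,
                "start_frame": s0,
                "end_frame": s1,
                "stride_length_m": L,
                "stride_time_s": T,
                "stance_pct": 100.0 * config.duty_factor,
                "swing_pct": 100.0 * (1.0 - config.duty_factor),
                "step_width_m": w,
                "speed_m_s": v,
            })

    angle_profiles = {
        side: _true_angle_profiles(
            config, side,
            phi=2 * np.pi * ((first[side] % stride_frames) / stride_frames))
        for side in ("left", "right")
    }

    gt = GaitGroundTruth(hs, to, params, angle_profiles, clean, stride_frames, config)

    rng = np.random.default_rng(config.seed)
    noisy_xyz = series_xyz
    if config.trajectory_noise_sd_m > 0:
        noisy_xyz = noisy_xyz + rng.normal(
            0.0, config.trajectory_noise_sd_m, size=series_xyz.shape)
    if config.missing_rate > 0:
        missing = rng.random(missing.shape) < config.missing_rate
        noisy_xyz = np.where(missing[..., None], np.nan, noisy_xyz)
    out = KeypointSeries3D(fps, tuple(skeleton.keypoints), noisy_xyz, missing,
                           "Y", skeleton)
    return out, gt


def _true_angle_profiles(config: GaitSimConfig, side: str,
                         phi: float = 0.0) -> dict[str, np.ndarray]:
    """Closed-form joint-angle profiles over one cycle (101 samples).

    Evaluated analytically from the same kinematic rules that generate the
    trajectories, on a dense in-cycle grid, independent of the analysis code.
    ``phi`` is the pelvis lateral-oscillation phase at the heel strike.
    """
    n_dense = CYCLE_SAMPLES
    tau_cycle = np.linspace(0.0, 1.0, n_dense)     # 0..100% of cycle
    stride_frames = int(round(config.stride_time_s * config.fps))
    T = stride_frames / config.fps
    d = config.duty_factor
    stance_s, swing_s = d * T, T - d * T
    L, w, v = config.stride_length_m, config.step_width_m, config.stride_length_m / (stride_frames / config.fps)
    z_sign = 1.0 if side == "left" else -1.0

    tt = tau_cycle * T                              # time since heel strike
    # heel relative to its anchor
    heel = np.zeros((n_dense, 3))
    heel[:, 1] = HEEL_HEIGHT
    heel[:, 2] = z_sign * w / 2.0
    in_swing = tt > stance_s
    tau_sw = np.clip((tt[in_swing] - stance_s) / swing_s, 0, 1)
    heel[in_swing, 0] += L * _minimum_jerk(tau_sw)
    heel[in_swing, 1] += SWING_CLEARANCE * np.sin(np.pi * tau_sw) ** 2
    pitch = np.zeros(n_dense)
    pitch[in_swing] = -FOOT_PITCH_AMPLITUDE * np.sin(2 * np.pi * tau_sw)
    toe = _rigid_foot_point(heel, pitch, np.array([config.foot_m, TOE_HEIGHT, 0.0]))
    ankle = _rigid_foot_point(heel, pitch, ANKLE_OFFSET)

    # pelvis relative to the same anchor.  At the strike (tt = 0) the anchor
    # sits L*d/2 ahead of the pelvis; the strike phase within the pelvis
    # oscillation cycle depends only on the side (antiphase legs).
    root = np.zeros((n_dense, 3))
    root[:, 0] = -L * d / 2.0 + v * tt
    root[:, 1] = config.pelvis_height_m + VERTICAL_OSC * np.sin(
        4 * np.pi * tt / T + 2 * phi)
    root[:, 2] = LATERAL_OSC * np.sin(2 * np.pi * tt / T + phi)
    hip = root.copy()
    hip[:, 2] += z_sign * w / 2.0
    knee = _solve_knee(hip, ankle, config.thigh_m, config.shank_m)

    tilt = math.radians(PELVIS_TILT_DEG)
    trunk_dir = np.array([math.sin(tilt), math.cos(tilt), 0.0])

    # pelvis frame: lateral is +z for left hips minus right hips (both hips
    # share the root's motion, so the hip-hip vector is exactly +/-z)
    lateral = np.array([0.0, 0.0, 1.0])
    up_ref = trunk_dir
    forward = np.cross(up_ref, lateral)
    forward /= np.linalg.norm(forward)
    up = np.cross(lateral, forward)

    thigh = knee - hip
    t_f = thigh @ forward
    t_u = thigh @ up
    t_l = thigh @ lateral
    hip_flexion = np.degrees(np.arctan2(t_f, -t_u))

    v1 = hip - knee
    v2 = ankle - knee
    cosk = np.clip(np.einsum("ij,ij->i", v1, v2)
                   / (np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)),
                   -1, 1)
    knee_flexion = 180.0 - np.degrees(np.arccos(cosk))

    shank = ankle - knee
    foot = toe - heel
    sn = shank / np.linalg.norm(shank, axis=1, keepdims=True)
    fn = foot / np.linalg.norm(foot, axis=1, keepdims=True)
    cross = np.cross(sn, fn)
    raw_ankle = np.degrees(np.arctan2(cross @ lateral,
                                      np.einsum("ij,ij->i", sn, fn)))
    # neutral reference: mid-stance (foot flat), same definition as analysis
    mid = (tt >= 0.2 * stance_s) & (tt <= 0.8 * stance_s)
    ankle_dorsiflexion = raw_ankle - float(np.mean(raw_ankle[mid]))

    away = t_l if side == "left" else -t_l
    hip_abduction = np.degrees(np.arctan2(away, -t_u))

    pelvis_tilt = np.full(n_dense, PELVIS_TILT_DEG)

    return {
        "hip_flexion": hip_flexion,
        "knee_flexion": knee_flexion,
        "ankle_dorsiflexion": ankle_dorsiflexion,
        "hip_abduction": hip_abduction,
        "pelvis_tilt": pelvis_tilt,
    }


# ---------------------------------------------------------------------------
# Virtual camera rig and rendering
# ---------------------------------------------------------------------------

def _look_at(position: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """World-to-camera R, t for a camera at ``position`` looking at ``target``
    (Y-up world)."""
    z = target - position
    z = z / np.linalg.norm(z)
    up = np.array([0.0, 1.0, 0.0])
    x = np.cross(z, up)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    R = np.stack([x, y, z])
    tvec = -R @ position
    return R, tvec


def default_camera_rig(n_cameras: int = 3,
                       image_size: tuple[int, int] = (1292, 964),
                       focal_px: float = 1100.0) -> list[CameraModel]:
    """Three-camera rig viewing a 6 m walkway from ~3-4 m away."""
    target = np.array([3.0, 1.0, 0.0])
    positions = [
        np.array([3.0, 1.6, 4.0]),
        np.array([-1.5, 1.6, 3.0]),
        np.array([7.5, 1.6, 3.0]),
    ][:n_cameras]
    cams = []
    w, h = image_size
    for i, pos in enumerate(positions):
        R, tvec = _look_at(pos, target)
        K = np.array([[focal_px, 0.0, w / 2.0],
                      [0.0, focal_px, h / 2.0],
                      [0.0, 0.0, 1.0]])
        cams.append(CameraModel(f"cam{i}", K, R, tvec,
                                distortion=np.zeros(4), image_size=(w, h)))
    return cams


def render_views(series: KeypointSeries3D, cameras: list[CameraModel],
                 pixel_noise_sd_px: float = 0.0, missing_rate: float = 0.0,
                 seed: int = 0) -> list[KeypointSeries2D]:
    """Project a 3D series into each camera with pixel noise and dropouts.

    Keypoints behind a camera are marked missing for that view only.
    """
    rng = np.random.default_rng(seed)
    out = []
    n_frames, n_kp = series.xyz.shape[:2]
    for cam in cameras:
        data = np.full((n_frames, n_kp, 3), np.nan)
        missing = np.ones((n_frames, n_kp), dtype=bool)
        pts = series.xyz.reshape(-1, 3)
        valid = ~np.isnan(pts).any(axis=1)
        campts = pts[valid] @ cam.rotation.T + cam.translation
        front = campts[:, 2] > 1e-9
        ok = np.zeros(pts.shape[0], dtype=bool)
        ok_idx = np.flatnonzero(valid)[front]
        ok[ok_idx] = True
        pix = np.full((pts.shape[0], 2), np.nan)
        if ok_idx.size:
            pix[ok] = project_many(cam, pts[ok])
        pix = pix.reshape(n_frames, n_kp, 2)
        ok = ok.reshape(n_frames, n_kp)
        if pixel_noise_sd_px > 0:
            pix = pix + rng.normal(0.0, pixel_noise_sd_px, size=pix.shape)
        conf = np.where(ok, 1.0, 0.0)
        if missing_rate > 0:
            dropped = rng.random(ok.shape) < missing_rate
            ok = ok & ~dropped
        data[..., :2] = np.where(ok[..., None], pix, np.nan)
        data[..., 2] = np.where(ok, conf, np.nan)
        missing = ~ok
        out.append(KeypointSeries2D(cam.camera_id, series.fps,
                                    tuple(series.keypoints), data, missing))
    return out


def config_to_dict(config: GaitSimConfig) -> dict:
    return asdict(config)
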