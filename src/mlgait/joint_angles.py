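"""Geometric joint-angle curves per gait cycle.

Five angles per cycle, time-normalized to 101 samples (0-100% of cycle):
hip flexion/extension, knee flexion/extension, ankle dorsi-/plantar-flexion,
hip ab-/ad-duction, and pelvis tilt.  Angles are measured directly from the
keypoint geometry in an anatomical pelvis frame (no musculoskeletal model);
signs follow gait-analysis convention (flexion / dorsiflexion / abduction /
anterior tilt positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from mlgait.errors import DataError
from mlgait.gait_events import GaitCycle
from mlgait.gait_params import walking_direction
from mlgait.preprocess import CYCLE_SAMPLES, interpolate_gaps, time_normalize
from mlgait.trajectory_io import KeypointSeries3D

ANGLE_NAMES = ("hip_flexion", "knee_flexion", "ankle_dorsiflexion",
               "hip_abduction", "pelvis_tilt")

SIGN_CONVENTIONS = {
    "hip_flexion": "thigh forward of pelvis 'down' axis positive",
    "knee_flexion": "0 deg at full extension, flexion positive",
    "ankle_dorsiflexion": "toes-up rotation positive, relative to neutral",
    "hip_abduction": "thigh away from midline positive",
    "pelvis_tilt": "anterior tilt positive",
}

#: Maximum fraction of a cycle a required keypoint may be missing.
MAX_MISSING_FRACTION = 0.2


@dataclass
class JointAngleCurves:
    """Five 101-sample joint-angle curves (degrees) for one cycle."""

    cycle: GaitCycle
    side: str
    curves: dict[str, np.ndarray]
    conventions: Mapping[str, str] = field(default_factory=lambda: dict(SIGN_CONVENTIONS))

    def __post_init__(self) -> None:
        for name in ANGLE_NAMES:
            if name not in self.curves:
                raise DataError(f"missing angle curve {name!r}")
            c = np.asarray(self.curves[name], float)
            if c.shape != (CYCLE_SAMPLES,) or not np.all(np.isfinite(c)):
                raise DataError(f"curve {name!r} must be {CYCLE_SAMPLES} finite samples")
            self.curves[name] = c


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    return v / n


def pelvis_frame(series: KeypointSeries3D, frame: int,
                 direction: np.ndarray | None = None
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Right-handed anatomical pelvis frame (forward, up, lateral) at a frame.

    Lateral runs right hip -> left hip.  The pelvis up axis comes from the
    pelvis-root-to-belly segment when a 'belly' keypoint exists (this is what
    makes pelvis tilt observable); otherwise the global vertical is used and
    pelvis tilt degenerates to zero.  ``forward`` is flipped, together with
    ``lateral``, to point along the walking direction when one is supplied.
    """
    frames = pelvis_frames(series, np.array([frame]), direction)
    return frames[0][0], frames[1][0], frames[2][0]


def pelvis_frames(series: KeypointSeries3D, frames: np.ndarray,
                  direction: np.ndarray | None = None
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized :func:`pelvis_frame`; returns (forward, up, lateral), each
    of shape (n, 3)."""
    lh = series.role_trajectory("left_hip")[frames]
    rh = series.role_trajectory("right_hip")[frames]
    hip_vec = lh - rh
    norms = np.linalg.norm(hip_vec, axis=1)
    if np.any(norms < 1e-9):
        raise DataError("hips coincide; pelvis frame undefined")
    lateral = hip_vec / norms[:, None]

    if "belly" in series.keypoints:
        root = series.role_trajectory("pelvis_root")[frames]
        belly = series.trajectory("belly")[frames]
        up_ref = _unit(belly - root)
    else:
        up_ref = np.broadcast_to(series.up_vector(), lateral.shape)

    forward = np.cross(up_ref, lateral)
    fn = np.linalg.norm(forward, axis=1)
    if np.any(fn < 1e-9):
        raise DataError("degenerate pelvis frame (up axis parallel to hip axis)")
    forward = forward / fn[:, None]
    up = np.cross(lateral, forward)

    if direction is not None:
        flip = (forward @ np.asarray(direction, float)) < 0
        forward[flip] *= -1
        lateral[flip] *= -1
    return forward, up, lateral


def _signed_angle_about(v_from: np.ndarray, v_to: np.ndarray,
                        axis: np.ndarray) -> np.ndarray:
    """Signed angle (deg) from ``v_from`` to ``v_to`` about ``axis``, rowwise."""
    v_from, v_to = _unit(v_from), _unit(v_to)
    cross = np.cross(v_from, v_to)
    sin_t = np.einsum("ij,ij->i", cross, axis)
    cos_t = np.einsum("ij,ij->i", v_from, v_to)
    return np.degrees(np.arctan2(sin_t, cos_t))


def _raw_ankle_angle(series: KeypointSeries3D, frames: np.ndarray, side: str,
                     lateral: np.ndarray) -> np.ndarray:
    """Shank-to-foot angle (deg) about the pelvis lateral axis; ~90 at neutral."""
    knee = series.role_trajectory(f"{side}_knee")[frames]
    ankle = series.role_trajectory(f"{side}_ankle")[frames]
    heel = series.role_trajectory(f"{side}_heel")[frames]
    toe = series.role_trajectory(f"{side}_toe")[frames]
    return _signed_angle_about(ankle - knee, toe - heel, lateral)


def ankle_neutral_reference(series: KeypointSeries3D, cycle: GaitCycle,
                            direction: np.ndarray | None = None) -> float:
    """Neutral (foot-flat) shank-foot angle from the cycle's mid-stance frames."""
    side = cycle.side
    stance = cycle.toe_off_frame - cycle.start_frame
    a = cycle.start_index + int(round(0.2 * stance))
    b = cycle.start_index + max(int(round(0.8 * stance)), int(round(0.2 * stance)) + 1)
    frames = np.arange(a, b)
    _, _, lateral = pelvis_frames(series, frames, direction)
    raw = _raw_ankle_angle(series, frames, side, lateral)
    return float(np.mean(raw))


def _check_missing(series: KeypointSeries3D, cycle: GaitCycle) -> KeypointSeries3D:
    side, other = cycle.side, ("right" if cycle.side == "left" else "left")
    roles = [f"{side}_hip", f"{side}_knee", f"{side}_ankle", f"{side}_heel",
             f"{side}_toe", f"{other}_hip", "pelvis_root"]
    sl = slice(cycle.start_index, cycle.end_index + 1)
    n = cycle.end_index - cycle.start_index + 1
    for role in roles:
        kp = series.skeleton.role_keypoint(role) if series.skeleton else role
        k = series.index(kp)
        frac = float(series.missing[sl, k].mean())
        if frac >= MAX_MISSING_FRACTION:
            raise DataError(
                f"keypoint {kp!r} missing for {frac:.0%} of the cycle (>= "
                f"{MAX_MISSING_FRACTION:.0%})")
    if series.missing.any():
        series, _ = interpolate_gaps(series, max_gap_frames=max(2, int(0.2 * n)))
    return series


def compute_joint_angles(series: KeypointSeries3D, cycle: GaitCycle,
                         direction: np.ndarray | None = None,
                         ankle_neutral_deg: float | None = None,
                         ankle_mode: str = "neutral") -> JointAngleCurves:
    """Compute the five angle curves for one cycle.

    The series is expected to be low-pass filtered (12 Hz).  ``ankle_mode``
    "neutral" subtracts the foot-flat reference angle (from
    ``ankle_neutral_deg`` if given, else this cycle's own mid-stance);
    "absolute" subtracts 90 degrees instead.
    """
    if cycle.end_index >= series.n_frames:
        raise DataError("cycle extends beyond the record")
    if direction is None:
        direction, _ = walking_direction(series)
    series = _check_missing(series, cycle)
    side = cycle.side
    frames = np.arange(cycle.start_index, cycle.end_index + 1)

    forward, up, lateral = pelvis_frames(series, frames, direction)
    up_global = series.up_vector()

    hip = series.role_trajectory(f"{side}_hip")[frames]
    knee = series.role_trajectory(f"{side}_knee")[frames]
    ankle = series.role_trajectory(f"{side}_ankle")[frames]
    thigh = knee - hip
    shank = ankle - knee

    # hip flexion: thigh angle from the pelvis "down" axis in the sagittal plane
    t_f = np.einsum("ij,ij->i", thigh, forward)
    t_u = np.einsum("ij,ij->i", thigh, up)
    hip_flexion = np.degrees(np.arctan2(t_f, -t_u))

    # knee flexion: 180 deg minus the angle at the knee
    v1, v2 = _unit(hip - knee), _unit(ankle - knee)
    cos_knee = np.clip(np.einsum("ij,ij->i", v1, v2), -1.0, 1.0)
    knee_flexion = 180.0 - np.degrees(np.arccos(cos_knee))

    # ankle dorsiflexion relative to neutral
    raw_ankle = _raw_ankle_angle(series, frames, side, lateral)
    if ankle_mode == "absolute":
        neutral = 90.0
    elif ankle_neutral_deg is not None:
        neutral = float(ankle_neutral_deg)
    else:
        neutral = ankle_neutral_reference(series, cycle, direction)
    ankle_dorsiflexion = raw_ankle - neutral

    # hip abduction: thigh angle from "down" in the frontal plane, away from midline
    t_l = np.einsum("ij,ij->i", thigh, lateral)
    away = t_l if side == "left" else -t_l
    hip_abduction = np.degrees(np.arctan2(away, -t_u))

    # pelvis tilt: forward axis dip below horizontal, anterior positive
    dip = np.clip(-(forward @ up_global), -1.0, 1.0)
    pelvis_tilt = np.degrees(np.arcsin(dip))

    curves = {
        "hip_flexion": time_normalize(hip_flexion),
        "knee_flexion": time_normalize(knee_flexion),
        "ankle_dorsiflexion": time_normalize(ankle_dorsiflexion),
        "hip_abduction": time_normalize(hip_abduction),
        "pelvis_tilt": time_normalize(pelvis_tilt),
    }
    return JointAngleCurves(cycle, side, curves)


def angles_table(all_curves: list[JointAngleCurves], layout: str = "long") -> pd.DataFrame:
    """Angle curves as a DataFrame; ``layout`` is 'long' or 'wide'."""
    if layout == "long":
        rows = []
        for i, jac in enumerate(all_curves):
            for name in ANGLE_NAMES:
                for pct, val in enumerate(jac.curves[name]):
                    rows.append((i, jac.side, name, pct, val))
        return pd.DataFrame(rows, columns=["cycle", "side", "angle", "pct", "value_deg"])
    if layout == "wide":
        rows = []
        for i, jac in enumerate(all_curves):
            for name in ANGLE_NAMES:
                rows.append({"cycle": i, "side": jac.side, "angle": name,
                             **{f"p{p}": v for p, v in enumerate(jac.curves[name])}})
        return pd.DataFrame(rows)
    raise DataError(f"unknown layout {layout!r}")
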