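"""Per-cycle spatio-temporal gait parameters.

Six parameters per gait cycle: stance %, swing %, stride length (m), stride
(step) width (m), stride time (s), and mean speed (m/s).  Lengths are
measured in the horizontal plane; the walking direction is estimated from
the pelvis-root displacement so all parameters are invariant to rotations
about the vertical axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mlgait.errors import DataError
from mlgait.gait_events import GaitCycle
from mlgait.preprocess import velocity
from mlgait.trajectory_io import KeypointSeries3D

#: Minimum net horizontal progression for a defined walking direction.
MIN_PROGRESSION_M = 0.5


@dataclass(frozen=True)
class SpatioTemporalParams:
    """The six per-cycle parameters (Table-2-style columns)."""

    side: str
    stride_length_m: float
    stride_time_s: float
    stance_pct: float
    swing_pct: float
    stride_width_m: float | None
    speed_m_s: float
    cycle: GaitCycle

    def __post_init__(self) -> None:
        if self.stride_length_m < 0 or (self.stride_width_m is not None
                                        and self.stride_width_m < 0):
            raise DataError("lengths must be non-negative")
        if self.stride_time_s <= 0:
            raise DataError("stride time must be positive")
        if self.speed_m_s < 0:
            raise DataError("speed must be non-negative")
        if abs(self.stance_pct + self.swing_pct - 100.0) > 1e-12:
            raise DataError("stance + swing must equal 100")


def _horizontal(series: KeypointSeries3D, vecs: np.ndarray) -> np.ndarray:
    """Zero out the vertical component of (..., 3) vectors."""
    out = np.array(vecs, float, copy=True)
    out[..., series.vertical_index] = 0.0
    return out


def walking_direction(series: KeypointSeries3D,
                      window: tuple[int, int] | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Unit horizontal progression and lateral vectors.

    Progression is the first principal axis of the horizontal pelvis-root
    positions, signed along the net displacement; lateral = up x progression.
    """
    root = series.role_trajectory("pelvis_root")
    if window is not None:
        root = root[window[0]:window[1]]
    valid = ~np.isnan(root).any(axis=1)
    root = root[valid]
    if root.shape[0] < 2:
        raise DataError("no progression: too few valid pelvis samples")
    h = _horizontal(series, root)
    net = h[-1] - h[0]
    if np.linalg.norm(net) < MIN_PROGRESSION_M:
        raise DataError(
            f"no progression: net horizontal displacement "
            f"{np.linalg.norm(net):.3f} m < {MIN_PROGRESSION_M} m")
    centered = h - h.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    direction[series.vertical_index] = 0.0
    direction = direction / np.linalg.norm(direction)
    if np.dot(direction, net) < 0:
        direction = -direction
    lateral = np.cross(series.up_vector(), direction)
    lateral /= np.linalg.norm(lateral)
    return direction, lateral


def compute_params(series: KeypointSeries3D, cycle: GaitCycle,
                   direction: np.ndarray | None = None,
                   lateral: np.ndarray | None = None) -> SpatioTemporalParams:
    """Compute the six parameters for one cycle.

    The series is expected to be gap-interpolated and low-pass filtered
    (12 Hz) already.  Stride length is the horizontal displacement of the
    ipsilateral heel between consecutive strikes; width is the cycle-mean
    absolute lateral heel separation; speed is the cycle-mean speed of the
    pelvis-root keypoint (center-of-mass proxy).
    """
    if cycle.end_index >= series.n_frames:
        raise DataError("cycle extends beyond the record")
    if direction is None or lateral is None:
        direction, lateral = walking_direction(series)

    side, other = cycle.side, ("right" if cycle.side == "left" else "left")
    heel = series.role_trajectory(f"{side}_heel")
    sl_vec = _horizontal(series, heel[cycle.end_index] - heel[cycle.start_index])
    if np.isnan(sl_vec).any():
        raise DataError("heel position missing at a cycle boundary")
    stride_length = float(np.linalg.norm(sl_vec))
    stride_time = cycle.duration_frames / series.fps
    stance_pct = 100.0 * cycle.stance_fraction
    swing_pct = 100.0 - stance_pct

    sl_frames = slice(cycle.start_index, cycle.end_index + 1)
    heel_other = series.role_trajectory(f"{other}_heel")
    sep = heel[sl_frames] - heel_other[sl_frames]
    lat = np.abs(sep @ lateral)
    lat = lat[~np.isnan(lat)]
    stride_width = float(np.mean(lat)) if lat.size else None

    root_idx = series.skeleton.role_index("pelvis_root") if series.skeleton \
        else series.index("pelvis")
    _, speeds = velocity(series)
    speed = float(np.mean(speeds[cycle.start_index:cycle.end_index, root_idx]))

    return SpatioTemporalParams(side, stride_length, stride_time, stance_pct,
                                swing_pct, stride_width, speed, cycle)


def params_table(params: list[SpatioTemporalParams],
                 subject: str = "", trial: str = "") -> pd.DataFrame:
    """One row per cycle, Table-2 column layout."""
    rows = [{
        "subject": subject, "trial": trial, "side": p.side,
        "stance_pct": p.stance_pct, "swing_pct": p.swing_pct,
        "stride_length_m": p.stride_length_m, "step_width_m": p.stride_width_m,
        "stride_time_s": p.stride_time_s, "speed_m_s": p.speed_m_s,
    } for p in params]
    return pd.DataFrame(rows)


def summarize_params(table: pd.DataFrame, by: list[str] | None = None) -> pd.DataFrame:
    """Mean +/- SD summary of the six parameters, optionally grouped."""
    cols = ["stance_pct", "swing_pct", "stride_length_m", "step_width_m",
            "stride_time_s", "speed_m_s"]
    if by:
        grouped = table.groupby(by)[cols]
        return grouped.agg(["mean", "std"])
    return table[cols].agg(["mean", "std"])
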