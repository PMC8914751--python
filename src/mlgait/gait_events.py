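"""Heel-strike / toe-off detection and gait-cycle segmentation.

Events come from the speed of the heel and toe keypoints: the heel speed is
near zero throughout stance and rises in swing, so heel strikes are onsets of
low-speed intervals and toe-offs are the frames where the toe speed rises
again after each stance onset.

Detection is two-stage.  Stage 1 locates low-speed intervals on the heavily
smoothed speed (4th-order zero-phase Butterworth at 3 Hz) with an adaptive
hysteresis threshold (a fraction of the record's 95th-percentile speed, so
detection is invariant to walking speed).  Stage 2 refines each event to
sub-frame precision by interpolating the threshold crossing of a lightly
smoothed speed (12 Hz), whose ramps are steep enough to localize the
zero-speed instant.  Public event lists are integer frames; cycle objects
keep the sub-frame estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from mlgait.errors import DataError
from mlgait.preprocess import interpolate_gaps, lowpass_array
from mlgait.trajectory_io import KeypointSeries3D

logger = logging.getLogger(__name__)

EVENT_CUTOFF_HZ = 3.0           # stage-1 low-pass cutoff
REFINE_CUTOFF_HZ = 12.0         # stage-2 low-pass cutoff
THRESHOLD_FRACTION = 0.15       # stage-1 falling threshold, fraction of p95
FALL_REFINE_FRACTION = 0.03     # stage-2 heel-strike crossing threshold
RISE_REFINE_FRACTION = 0.07     # stage-2 toe-off crossing threshold
HYSTERESIS = 1.25               # rising / falling threshold ratio
MIN_STANCE_S = 0.1              # minimum low-speed interval duration
MIN_ACTIVITY_SPEED = 0.1        # m/s; below this p95 the record is "no gait"


@dataclass(frozen=True)
class GaitCycle:
    """One heel-strike-to-heel-strike segment of one side.

    Event positions are sub-frame (float) estimates; ``*_index`` properties
    give the nearest integer frames for array indexing.
    """

    side: str                   # "left" | "right"
    start_frame: float          # heel strike
    end_frame: float            # next ipsilateral heel strike
    toe_off_frame: float
    is_central: bool = False
    toe_off_from_heel: bool = False   # toe keypoint absent; heel fallback used

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise DataError(f"invalid side {self.side!r}")
        if not (self.start_frame < self.toe_off_frame < self.end_frame):
            raise DataError(
                f"cycle invariant violated: start {self.start_frame} < toe_off "
                f"{self.toe_off_frame} < end {self.end_frame} required")

    @property
    def stance_fraction(self) -> float:
        return (self.toe_off_frame - self.start_frame) / (self.end_frame - self.start_frame)

    @property
    def swing_fraction(self) -> float:
        return 1.0 - self.stance_fraction

    @property
    def start_index(self) -> int:
        return int(round(self.start_frame))

    @property
    def end_index(self) -> int:
        return int(round(self.end_frame))

    @property
    def toe_off_index(self) -> int:
        return int(round(self.toe_off_frame))

    @property
    def duration_frames(self) -> float:
        return self.end_frame - self.start_frame


def _filtered_speed(series: KeypointSeries3D, keypoint: str,
                    cutoff_hz: float) -> np.ndarray:
    filled, _ = interpolate_gaps(series, max_gap_frames=series.n_frames)
    traj = filled.trajectory(keypoint)
    cutoff = min(cutoff_hz, 0.45 * series.fps)
    smooth = lowpass_array(traj, series.fps, cutoff, order=4, zero_phase=True)
    vel = np.gradient(smooth, 1.0 / series.fps, axis=0)
    return np.linalg.norm(vel, axis=1)


def _heel_keypoint(series: KeypointSeries3D, side: str) -> str:
    return (series.skeleton.role_keypoint(f"{side}_heel")
            if series.skeleton else f"{side}_heel")


def _toe_keypoint(series: KeypointSeries3D, side: str) -> str | None:
    try:
        kp = (series.skeleton.role_keypoint(f"{side}_toe")
              if series.skeleton else f"{side}_toe")
        series.index(kp)
        return kp
    except DataError:
        return None


def _low_speed_intervals(speed: np.ndarray, fall_thr: float, rise_thr: float
                         ) -> list[tuple[int, int]]:
    """Hysteresis segmentation into low-speed (stance candidate) intervals."""
    intervals: list[tuple[int, int]] = []
    low = speed[0] < fall_thr
    start = 0 if low else -1
    for i in range(1, speed.size):
        if low:
            if speed[i] > rise_thr:
                intervals.append((start, i))
                low = False
        else:
            if speed[i] < fall_thr:
                start = i
                low = True
    if low:
        intervals.append((start, speed.size))
    return intervals


def _noise_floor(fine: np.ndarray, intervals: list[tuple[int, int]]) -> float:
    """Median fine-filtered speed inside stance intervals, where the true
    speed is ~0; used to keep refinement thresholds above the noise."""
    samples = []
    for a, b in intervals:
        if b - a > 6:
            samples.append(fine[a + 3:b - 3])
    if not samples:
        return 0.0
    return float(np.median(np.concatenate(samples)))


def _interp_fall(speed: np.ndarray, thr: float, lo: int, hi: int) -> float | None:
    """Sub-frame crossing where ``speed`` falls below ``thr`` in [lo, hi)."""
    for k in range(max(lo, 1), min(hi, speed.size)):
        if speed[k] < thr <= speed[k - 1]:
            return (k - 1) + (speed[k - 1] - thr) / (speed[k - 1] - speed[k])
    return None


def _interp_rise_backward(speed: np.ndarray, thr: float, hi: int, lo: int) -> float | None:
    """Sub-frame crossing where ``speed`` last rose through ``thr`` at or
    before ``hi``, searching backward down to ``lo``."""
    for k in range(min(hi, speed.size - 2), max(lo, 0), -1):
        if speed[k] < thr <= speed[k + 1]:
            return k + (thr - speed[k]) / (speed[k + 1] - speed[k])
    return None


def detect_heel_strikes_subframe(series: KeypointSeries3D, side: str,
                                 event_cutoff_hz: float = EVENT_CUTOFF_HZ,
                                 threshold_fraction: float = THRESHOLD_FRACTION,
                                 min_stance_s: float = MIN_STANCE_S) -> list[float]:
    """Sub-frame heel-strike positions for one side (see module docstring)."""
    if side not in ("left", "right"):
        raise DataError(f"invalid side {side!r}")
    if series.n_frames < series.fps:  # < 1 s of data
        logger.warning("record shorter than 1 s; no gait detected")
        return []
    heel = _heel_keypoint(series, side)
    coarse = _filtered_speed(series, heel, event_cutoff_hz)
    p95 = float(np.percentile(coarse, 95))
    if p95 < MIN_ACTIVITY_SPEED:
        logger.warning("no gait detected: heel speed p95 = %.4f m/s", p95)
        return []
    fall_thr = threshold_fraction * p95
    rise_thr = HYSTERESIS * fall_thr
    min_len = int(round(min_stance_s * series.fps))
    intervals = [(a, b) for a, b in _low_speed_intervals(coarse, fall_thr, rise_thr)
                 if b - a >= min_len]
    if not intervals:
        logger.warning("no gait detected: no low-speed interval >= %.2f s", min_stance_s)
        return []

    fine = _filtered_speed(series, heel, REFINE_CUTOFF_HZ)
    fine_thr = max(FALL_REFINE_FRACTION * float(np.percentile(fine, 95)),
                   2.0 * _noise_floor(fine, intervals))
    strikes: list[float] = []
    for a, b in intervals:
        if a == 0:
            # stance already in progress at record start: not an observed strike
            continue
        t0 = _interp_fall(fine, fine_thr, a - 2, b)
        strikes.append(float(t0) if t0 is not None else float(a))
    return strikes


def detect_heel_strikes(series: KeypointSeries3D, side: str,
                        event_cutoff_hz: float = EVENT_CUTOFF_HZ,
                        threshold_fraction: float = THRESHOLD_FRACTION,
                        min_stance_s: float = MIN_STANCE_S) -> list[int]:
    """Heel-strike frames for one side, strictly increasing.

    Returns an empty list (with a logged diagnostic) when no gait is present;
    never raises for degenerate motion content.
    """
    sub = detect_heel_strikes_subframe(series, side, event_cutoff_hz,
                                       threshold_fraction, min_stance_s)
    out: list[int] = []
    for s in sub:
        k = int(round(s))
        if not out or k > out[-1]:
            out.append(k)
    return out


def detect_toe_off_subframe(series: KeypointSeries3D, side: str,
                            heel_strikes: list[float],
                            event_cutoff_hz: float = EVENT_CUTOFF_HZ,
                            threshold_fraction: float = THRESHOLD_FRACTION
                            ) -> list[float]:
    """Sub-frame toe-off positions, one strictly inside each strike pair."""
    if len(heel_strikes) < 2:
        return []
    kp = _toe_keypoint(series, side)
    if kp is None:
        kp = _heel_keypoint(series, side)
        logger.warning("no %s toe keypoint; falling back to heel speed for toe-off", side)
    coarse = _filtered_speed(series, kp, event_cutoff_hz)
    p95 = float(np.percentile(coarse, 95))
    full_thr = threshold_fraction * p95
    fine = _filtered_speed(series, kp, REFINE_CUTOFF_HZ)
    dwell_intervals = _low_speed_intervals(coarse, full_thr, HYSTERESIS * full_thr)
    fine_thr = max(RISE_REFINE_FRACTION * float(np.percentile(fine, 95)),
                   2.0 * _noise_floor(fine, dwell_intervals))
    out: list[float] = []
    for start, end in zip(heel_strikes[:-1], heel_strikes[1:]):
        i0, i1 = int(np.ceil(start)), int(np.floor(end))
        seg = coarse[i0:i1]
        toe_off = start + (end - start) / 2.0  # degenerate fallback
        # the foot settles shortly after the strike; find the low dwell, then
        # a rise through the full threshold (landing ripple stays below it)
        low = np.flatnonzero(seg < full_thr)
        if low.size:
            dwell = int(low[0])
            above = np.flatnonzero(seg[dwell:] > full_thr)
            if above.size:
                k1 = i0 + dwell + int(above[0])
                t0 = _interp_rise_backward(fine, fine_thr, k1, i0 + dwell - 1)
                if t0 is not None:
                    toe_off = t0
        toe_off = float(np.clip(toe_off, np.nextafter(start, end),
                                np.nextafter(end, start)))
        out.append(toe_off)
    return out


def detect_toe_off(series: KeypointSeries3D, side: str,
                   heel_strikes: list[int],
                   event_cutoff_hz: float = EVENT_CUTOFF_HZ,
                   threshold_fraction: float = THRESHOLD_FRACTION) -> list[int]:
    """One toe-off frame strictly inside each (strike, next-strike) cycle.

    Uses the toe keypoint's filtered speed rising through the adaptive
    threshold; falls back to the heel speed (logged) when no toe keypoint is
    bound for the side.
    """
    sub = detect_toe_off_subframe(series, side, [float(h) for h in heel_strikes],
                                  event_cutoff_hz, threshold_fraction)
    out = []
    for s, e, t in zip(heel_strikes[:-1], heel_strikes[1:], sub):
        out.append(int(np.clip(round(t), s + 1, e - 1)))
    return out


def segment_cycles(series: KeypointSeries3D,
                   event_cutoff_hz: float = EVENT_CUTOFF_HZ,
                   threshold_fraction: float = THRESHOLD_FRACTION) -> list[GaitCycle]:
    """Build gait cycles for both sides; flags the central cycle per side.

    The central cycle is the one whose midpoint is nearest the record
    midpoint (the one used for single-cycle reporting).
    """
    cycles: list[GaitCycle] = []
    mid_record = series.n_frames / 2.0
    for side in ("left", "right"):
        strikes = detect_heel_strikes_subframe(series, side, event_cutoff_hz,
                                               threshold_fraction)
        toe_offs = detect_toe_off_subframe(series, side, strikes,
                                           event_cutoff_hz, threshold_fraction)
        fallback = _toe_keypoint(series, side) is None
        side_cycles = [
            GaitCycle(side, s, e, t, toe_off_from_heel=fallback)
            for s, e, t in zip(strikes[:-1], strikes[1:], toe_offs)
        ]
        if side_cycles:
            mids = [0.5 * (c.start_frame + c.end_frame) for c in side_cycles]
            central = int(np.argmin(np.abs(np.asarray(mids) - mid_record)))
            c = side_cycles[central]
            side_cycles[central] = GaitCycle(c.side, c.start_frame, c.end_frame,
                                             c.toe_off_frame, is_central=True,
                                             toe_off_from_heel=fallback)
        cycles.extend(side_cycles)
    return cycles


def events_table(cycles: list[GaitCycle], fps: float):
    """Long-format events table (side, event_type, frame, time_s)."""
    import pandas as pd

    rows = []
    for c in cycles:
        rows.append((c.side, "heel_strike", c.start_index, c.start_frame / fps))
        rows.append((c.side, "toe_off", c.toe_off_index, c.toe_off_frame / fps))
        rows.append((c.side, "heel_strike", c.end_index, c.end_frame / fps))
    df = pd.DataFrame(rows, columns=["side", "event_type", "frame", "time_s"])
    return df.drop_duplicates().sort_values(["frame", "side"]).reset_index(drop=True)
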