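"""Temporal filtering, gap interpolation, differentiation, time-normalization.

All operations act per keypoint, per coordinate.  The low-pass filter is a
zero-phase (forward-backward) Butterworth so event timing is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt

from mlgait.errors import ConfigError, DataError, MissingDataError
from mlgait.trajectory_io import KeypointSeries3D

#: Number of samples in a time-normalized gait-cycle curve (0..100% inclusive).
CYCLE_SAMPLES = 101


def lowpass_array(data: np.ndarray, fps: float, cutoff_hz: float,
                  order: int = 4, zero_phase: bool = True,
                  effective_order: bool = False) -> np.ndarray:
    """Butterworth low-pass along axis 0.

    ``order`` is the order of the designed filter.  With ``zero_phase`` the
    filter is applied forward and backward (squared magnitude response, no
    phase lag); set ``effective_order`` to design at order/2 so the combined
    response has the nominal order.
    """
    if cutoff_hz <= 0:
        raise ConfigError("cutoff must be positive")
    nyquist = fps / 2.0
    if cutoff_hz >= nyquist:
        raise ConfigError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyquist} Hz")
    design_order = order
    if effective_order:
        if order % 2:
            raise ConfigError("effective_order requires an even order")
        design_order = order // 2
    b, a = butter(design_order, cutoff_hz / nyquist)
    data = np.asarray(data, float)
    if np.isnan(data).any():
        raise MissingDataError("filtering requires gap-free data; run interpolate_gaps first")
    if not zero_phase:
        from scipy.signal import lfilter
        return lfilter(b, a, data, axis=0)
    padlen = min(3 * max(len(a), len(b)) * 4, data.shape[0] - 1)
    return filtfilt(b, a, data, axis=0, padtype="even", padlen=padlen)


def butterworth_lowpass(series: KeypointSeries3D, cutoff_hz: float,
                        order: int = 4, zero_phase: bool = True,
                        effective_order: bool = False) -> KeypointSeries3D:
    """Zero-phase Butterworth low-pass of every keypoint trajectory."""
    if series.missing.any():
        raise MissingDataError(
            "series has missing samples; run interpolate_gaps before filtering")
    flat = series.xyz.reshape(series.n_frames, -1)
    filtered = lowpass_array(flat, series.fps, cutoff_hz, order=order,
                             zero_phase=zero_phase, effective_order=effective_order)
    return series.with_xyz(filtered.reshape(series.xyz.shape))


@dataclass(frozen=True)
class GapReport:
    """Gaps left unfilled by :func:`interpolate_gaps`."""

    unfilled: tuple[tuple[str, int, int], ...]  # (keypoint, start_frame, end_frame_excl)

    @property
    def clean(self) -> bool:
        return not self.unfilled


def _gaps(valid: np.ndarray) -> list[tuple[int, int]]:
    """Runs of False in a boolean vector as (start, end_exclusive)."""
    out = []
    n = valid.size
    i = 0
    while i < n:
        if not valid[i]:
            j = i
            while j < n and not valid[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def interpolate_gaps(series: KeypointSeries3D,
                     max_gap_frames: int = 10) -> tuple[KeypointSeries3D, GapReport]:
    """Fill interior gaps up to ``max_gap_frames`` with a cubic spline.

    Edge gaps are held constant at the nearest valid sample.  Longer interior
    gaps stay missing and are reported.  A keypoint with no valid sample at
    all is an error.
    """
    xyz = series.xyz.copy()
    missing = series.missing.copy()
    unfilled: list[tuple[str, int, int]] = []
    n = series.n_frames
    for k, name in enumerate(series.keypoints):
        valid = ~missing[:, k]
        if not valid.any():
            raise DataError(f"keypoint {name!r} has no valid samples")
        if valid.all():
            continue
        idx = np.flatnonzero(valid)
        spline = None
        if idx.size >= 2:
            spline = CubicSpline(idx, xyz[idx, k, :], axis=0)
        for start, end in _gaps(valid):
            if start == 0:  # leading edge: hold first valid value
                xyz[start:end, k, :] = xyz[idx[0], k, :]
                missing[start:end, k] = False
            elif end == n:  # trailing edge: hold last valid value
                xyz[start:end, k, :] = xyz[idx[-1], k, :]
                missing[start:end, k] = False
            elif end - start <= max_gap_frames and spline is not None:
                fill = np.arange(start, end)
                xyz[start:end, k, :] = spline(fill)
                missing[start:end, k] = False
            else:
                unfilled.append((name, start, end))
    out = series.with_xyz(xyz, missing)
    return out, GapReport(tuple(unfilled))


def velocity(series: KeypointSeries3D) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample velocity (m/s) and speed magnitude.

    Central differences in the interior, one-sided at the edges.
    Returns ``(vel, speed)`` with shapes (frames, K, 3) and (frames, K).
    """
    if series.n_frames < 2:
        raise DataError("velocity requires at least 2 frames")
    if series.missing.any():
        raise MissingDataError("velocity requires gap-free data")
    vel = np.gradient(series.xyz, 1.0 / series.fps, axis=0)
    speed = np.linalg.norm(vel, axis=2)
    return vel, speed


def time_normalize(curve: np.ndarray, n_samples: int = CYCLE_SAMPLES) -> np.ndarray:
    """Linearly resample a per-frame curve onto ``n_samples`` points spanning
    0-100% of the cycle; endpoints are preserved exactly."""
    curve = np.asarray(curve, float)
    n = curve.shape[0]
    if n < 4:
        raise DataError(f"time_normalize needs >=4 samples, got {n}")
    if n == n_samples:
        return curve.copy()
    x_old = np.linspace(0.0, 1.0, n)
    x_new = np.linspace(0.0, 1.0, n_samples)
    if curve.ndim == 1:
        out = np.interp(x_new, x_old, curve)
    else:
        out = np.stack([np.interp(x_new, x_old, curve[:, j])
                        for j in range(curve.shape[1])], axis=1)
    out[0] = curve[0]
    out[-1] = curve[-1]
    return out
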