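"""Keypoint-estimate evaluation metrics: PCKh@tau and MPJPE.

PCKh counts an estimate as correct when its Euclidean distance to the ground
truth is *strictly* less than tau times the head-segment reference length
(ties count as incorrect).  MPJPE is the mean Euclidean distance over all
valid (frame, keypoint) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mlgait.errors import DataError
from mlgait.trajectory_io import KeypointSeries3D, SkeletonDefinition


@dataclass
class MetricInput:
    """Aligned estimate / ground-truth arrays plus the reference length.

    ``estimates`` and ``ground_truth`` are (frames, keypoints, dims) with
    dims 2 or 3; ``reference_length`` is a scalar or per-frame array (the
    head-segment length h); ``missing`` marks samples excluded pairwise.
    """

    estimates: np.ndarray
    ground_truth: np.ndarray
    reference_length: float | np.ndarray = 1.0
    missing: np.ndarray | None = None
    keypoints: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.estimates = np.asarray(self.estimates, float)
        self.ground_truth = np.asarray(self.ground_truth, float)
        if self.estimates.shape != self.ground_truth.shape:
            raise DataError("estimate / ground-truth shape mismatch")
        if self.estimates.ndim != 3 or self.estimates.shape[2] not in (2, 3):
            raise DataError("inputs must be (frames, keypoints, 2 or 3)")
        ref = np.asarray(self.reference_length, float)
        if np.any(ref <= 0):
            raise DataError("reference length must be positive")
        if ref.ndim == 1 and ref.shape[0] != self.estimates.shape[0]:
            raise DataError("per-frame reference length has wrong length")
        if self.missing is None:
            self.missing = np.zeros(self.estimates.shape[:2], dtype=bool)
        else:
            self.missing = np.asarray(self.missing, bool)
            if self.missing.shape != self.estimates.shape[:2]:
                raise DataError("missing mask shape mismatch")
        # NaNs in either array are treated as missing pairwise
        nan_mask = (np.isnan(self.estimates).any(axis=2)
                    | np.isnan(self.ground_truth).any(axis=2))
        self.missing = self.missing | nan_mask

    @property
    def distances(self) -> np.ndarray:
        """(frames, keypoints) Euclidean distances; NaN where missing."""
        d = np.linalg.norm(self.estimates - self.ground_truth, axis=2)
        return np.where(self.missing, np.nan, d)


@dataclass(frozen=True)
class PCKhResult:
    tau: float
    overall_pct: float                       # pooled over all valid samples
    per_keypoint_pct: dict[str, float]
    mean_of_keypoints_pct: float             # unweighted mean of per-keypoint values
    n_valid: int


def pckh(metric_input: MetricInput, tau: float) -> PCKhResult:
    """PCKh@tau in percent, per keypoint and pooled.

    2D inputs expected (the metric evaluates an image-plane detector), but
    the formula is dimension-agnostic.
    """
    if tau <= 0:
        raise DataError("tau must be positive")
    d = metric_input.distances
    ref = np.asarray(metric_input.reference_length, float)
    thr = tau * (ref[:, None] if ref.ndim == 1 else ref)
    valid = ~metric_input.missing
    if not valid.any():
        raise DataError("no valid samples")
    correct = (d < thr) & valid

    overall = 100.0 * correct.sum() / valid.sum()
    names = metric_input.keypoints or tuple(
        f"kp{i}" for i in range(d.shape[1]))
    per_kp: dict[str, float] = {}
    for k, name in enumerate(names):
        nv = valid[:, k].sum()
        per_kp[name] = float(100.0 * correct[:, k].sum() / nv) if nv else float("nan")
    finite = [v for v in per_kp.values() if np.isfinite(v)]
    mean_kp = float(np.mean(finite)) if finite else float("nan")
    return PCKhResult(tau, float(overall), per_kp, mean_kp, int(valid.sum()))


@dataclass(frozen=True)
class MPJPEResult:
    overall: float
    per_keypoint: dict[str, float]
    n_valid: int


def mpjpe(metric_input: MetricInput) -> MPJPEResult:
    """Mean per-joint position error in the input units."""
    if metric_input.estimates.shape[2] != 3:
        raise DataError("MPJPE expects 3D inputs")
    d = metric_input.distances
    valid = ~metric_input.missing
    if not valid.any():
        raise DataError("no valid samples")
    overall = float(np.nanmean(d))
    names = metric_input.keypoints or tuple(f"kp{i}" for i in range(d.shape[1]))
    per_kp = {}
    for k, name in enumerate(names):
        col = d[:, k]
        per_kp[name] = float(np.nanmean(col)) if valid[:, k].any() else float("nan")
    return MPJPEResult(overall, per_kp, int(valid.sum()))


def head_reference_length(series: KeypointSeries3D | np.ndarray,
                          skeleton: SkeletonDefinition | None = None) -> float:
    """Per-record mean distance between the head-segment endpoints."""
    if isinstance(series, KeypointSeries3D):
        skeleton = skeleton or series.skeleton
        if skeleton is None:
            raise DataError("no skeleton to resolve the head segment")
        a = series.trajectory(skeleton.role_keypoint("head_top"))
        b = series.trajectory(skeleton.role_keypoint("head_ref"))
    else:
        raise DataError("head_reference_length expects a KeypointSeries3D")
    d = np.linalg.norm(a - b, axis=1)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise DataError("head segment never observed")
    length = float(np.mean(d))
    if length <= 0:
        raise DataError("zero head-segment reference length")
    return length
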