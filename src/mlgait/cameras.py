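"""Pinhole camera model, projection, and multi-view triangulation.

World coordinates are meters.  The distortion model is Brown-Conrady with
radial (k1, k2) and tangential (p1, p2) terms; observations are undistorted
before the linear (DLT) solve, and an optional least-squares refinement
minimises confidence-weighted reprojection error in pixels.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.optimize import least_squares

from mlgait.errors import (
    BehindCameraError,
    ConfigError,
    DataError,
    DegenerateGeometryError,
    InsufficientViewsError,
)
from mlgait.trajectory_io import KeypointSeries2D, KeypointSeries3D, SkeletonDefinition

logger = logging.getLogger(__name__)

#: Pairwise ray angles below this are treated as carrying no parallax at all.
_PARALLEL_RAY_DEG = 0.01
#: Below this ray angle (or above the condition-number cap) the solution is
#: still returned but flagged unreliable.
_MIN_RAY_ANGLE_DEG = 1.0
_MAX_CONDITION = 1e8


@dataclass(frozen=True)
class CameraModel:
    """Calibrated pinhole camera (world-to-camera extrinsics)."""

    camera_id: str
    intrinsics: np.ndarray          # 3x3 upper-triangular K
    rotation: np.ndarray            # 3x3 world-to-camera R
    translation: np.ndarray         # world-to-camera t, meters
    distortion: np.ndarray = field(default_factory=lambda: np.zeros(4))  # k1,k2,p1,p2
    image_size: tuple[int, int] = (1292, 964)  # width, height

    def __post_init__(self) -> None:
        object.__setattr__(self, "intrinsics", np.asarray(self.intrinsics, float).reshape(3, 3))
        object.__setattr__(self, "rotation", np.asarray(self.rotation, float).reshape(3, 3))
        object.__setattr__(self, "translation", np.asarray(self.translation, float).reshape(3))
        object.__setattr__(self, "distortion", np.asarray(self.distortion, float).reshape(4))
        K, R = self.intrinsics, self.rotation
        if K[0, 0] <= 0 or K[1, 1] <= 0:
            raise ConfigError(f"camera {self.camera_id!r}: focal lengths must be positive")
        if abs(K[1, 0]) > 0 or abs(K[2, 0]) > 0 or abs(K[2, 1]) > 0 or abs(K[2, 2] - 1) > 1e-12:
            raise ConfigError(f"camera {self.camera_id!r}: K must be upper-triangular with K[2,2]=1")
        if np.max(np.abs(R @ R.T - np.eye(3))) > 1e-8 or abs(np.linalg.det(R) - 1) > 1e-8:
            raise ConfigError(f"camera {self.camera_id!r}: rotation must be orthonormal, det +1")
        w, h = self.image_size
        if not (0 <= K[0, 2] <= w and 0 <= K[1, 2] <= h):
            raise ConfigError(f"camera {self.camera_id!r}: principal point outside image")

    @property
    def center(self) -> np.ndarray:
        """Camera center in world coordinates."""
        return -self.rotation.T @ self.translation


@dataclass(frozen=True)
class Observation2D:
    """A single 2D keypoint observation in one camera."""

    camera_id: str
    pixel: tuple[float, float]
    confidence: float | None = None

    def __post_init__(self) -> None:
        u, v = self.pixel
        if not (math.isfinite(u) and math.isfinite(v)):
            raise DataError("observation pixel coordinates must be finite")
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise DataError(f"confidence {self.confidence} outside [0, 1]")


@dataclass(frozen=True)
class TriangulationResult:
    point: np.ndarray
    rms_reprojection_error: float
    reliable: bool = True


def _distort(x: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Apply Brown-Conrady distortion to normalized coords (..., 2)."""
    k1, k2, p1, p2 = dist
    xs, ys = x[..., 0], x[..., 1]
    r2 = xs * xs + ys * ys
    radial = 1.0 + k1 * r2 + k2 * r2 * r2
    xd = xs * radial + 2 * p1 * xs * ys + p2 * (r2 + 2 * xs * xs)
    yd = ys * radial + p1 * (r2 + 2 * ys * ys) + 2 * p2 * xs * ys
    return np.stack([xd, yd], axis=-1)


def _undistort(xd: np.ndarray, dist: np.ndarray, iterations: int = 30) -> np.ndarray:
    """Invert the distortion by fixed-point iteration on normalized coords."""
    if not np.any(dist):
        return np.asarray(xd, float)
    x = np.asarray(xd, float).copy()
    k1, k2, p1, p2 = dist
    for _ in range(iterations):
        xs, ys = x[..., 0], x[..., 1]
        r2 = xs * xs + ys * ys
        radial = 1.0 + k1 * r2 + k2 * r2 * r2
        dx = 2 * p1 * xs * ys + p2 * (r2 + 2 * xs * xs)
        dy = p1 * (r2 + 2 * ys * ys) + 2 * p2 * xs * ys
        x = np.stack([(xd[..., 0] - dx) / radial, (xd[..., 1] - dy) / radial], axis=-1)
    return x


def project(camera: CameraModel, point: Sequence[float]) -> tuple[float, float]:
    """Project a world point to (distorted) pixel coordinates.

    Raises :class:`BehindCameraError` for non-positive depth.
    """
    pts = np.atleast_2d(np.asarray(point, float))
    pix = project_many(camera, pts)
    u, v = pix[0]
    return float(u), float(v)


def project_many(camera: CameraModel, points: np.ndarray) -> np.ndarray:
    """Vectorized projection of (..., 3) world points to (..., 2) pixels."""
    points = np.asarray(points, float)
    cam = points @ camera.rotation.T + camera.translation
    z = cam[..., 2]
    if np.any(z <= 0):
        raise BehindCameraError(
            f"camera {camera.camera_id!r}: point behind camera (depth <= 0)")
    xn = cam[..., :2] / z[..., None]
    xd = _distort(xn, camera.distortion)
    K = camera.intrinsics
    u = K[0, 0] * xd[..., 0] + K[0, 1] * xd[..., 1] + K[0, 2]
    v = K[1, 1] * xd[..., 1] + K[1, 2]
    return np.stack([u, v], axis=-1)


def pixel_to_normalized(camera: CameraModel, pixel: np.ndarray) -> np.ndarray:
    """Undistorted normalized image coordinates for (..., 2) pixels."""
    pixel = np.asarray(pixel, float)
    K = camera.intrinsics
    yd = (pixel[..., 1] - K[1, 2]) / K[1, 1]
    xd = (pixel[..., 0] - K[0, 2] - K[0, 1] * yd) / K[0, 0]
    return _undistort(np.stack([xd, yd], axis=-1), camera.distortion)


def reprojection_error(camera: CameraModel, point: Sequence[float],
                       observation: Observation2D) -> float:
    """Euclidean pixel distance between the projection of ``point`` and the
    observed pixel."""
    u, v = project(camera, point)
    ou, ov = observation.pixel
    return float(math.hypot(u - ou, v - ov))


def _ray_directions(cams: list[CameraModel], xn: np.ndarray) -> np.ndarray:
    dirs = []
    for cam, x in zip(cams, xn):
        d = cam.rotation.T @ np.array([x[0], x[1], 1.0])
        dirs.append(d / np.linalg.norm(d))
    return np.asarray(dirs)


def _max_pairwise_angle_deg(dirs: np.ndarray) -> float:
    best = 0.0
    for i in range(len(dirs)):
        for j in range(i + 1, len(dirs)):
            c = float(np.clip(abs(np.dot(dirs[i], dirs[j])), -1.0, 1.0))
            best = max(best, math.degrees(math.acos(c)))
    return best


def triangulate(observations: Sequence[Observation2D],
                cameras: Mapping[str, CameraModel],
                refine: bool = True,
                weight_by_confidence: bool = True) -> TriangulationResult:
    """Triangulate a 3D point from >=2 observations in distinct cameras.

    Linear DLT (SVD of the stacked cross-product constraints on undistorted
    normalized coordinates), optionally followed by Levenberg-Marquardt
    refinement of confidence-weighted squared reprojection error.
    """
    seen = {obs.camera_id for obs in observations}
    if len(seen) < 2:
        raise InsufficientViewsError(
            f"triangulation needs >=2 distinct camera views, got {len(seen)}")
    cams: list[CameraModel] = []
    for obs in observations:
        try:
            cams.append(cameras[obs.camera_id])
        except KeyError:
            raise DataError(f"no calibration for camera {obs.camera_id!r}") from None
    pixels = np.array([obs.pixel for obs in observations], float)
    weights = np.array([1.0 if obs.confidence is None else obs.confidence
                        for obs in observations])
    if not weight_by_confidence:
        weights = np.ones_like(weights)

    xn = np.array([pixel_to_normalized(cam, px) for cam, px in zip(cams, pixels)])

    dirs = _ray_directions(cams, xn)
    max_angle = _max_pairwise_angle_deg(dirs)
    if max_angle < _PARALLEL_RAY_DEG:
        raise DegenerateGeometryError(
            f"rays are parallel (max pairwise angle {max_angle:.4f} deg); no parallax")

    # DLT on normalized coordinates: rows x*(p3.X) - p1.X, y*(p3.X) - p2.X
    rows = []
    for cam, x, w in zip(cams, xn, np.sqrt(np.maximum(weights, 1e-12))):
        P = np.hstack([cam.rotation, cam.translation[:, None]])
        rows.append(w * (x[0] * P[2] - P[0]))
        rows.append(w * (x[1] * P[2] - P[1]))
    A = np.asarray(rows)
    _, s, vt = np.linalg.svd(A)
    X_h = vt[-1]
    cond = float(s[0] / s[-2]) if s[-2] > 0 else np.inf
    reliable = max_angle >= _MIN_RAY_ANGLE_DEG and cond <= _MAX_CONDITION
    if abs(X_h[3]) < 1e-15:
        raise DegenerateGeometryError("DLT produced a point at infinity")
    point = X_h[:3] / X_h[3]

    def residuals(p: np.ndarray) -> np.ndarray:
        res = np.empty(2 * len(cams))
        for i, (cam, px, w) in enumerate(zip(cams, pixels, weights)):
            camp = cam.rotation @ p + cam.translation
            if camp[2] <= 1e-9:
                res[2 * i:2 * i + 2] = 1e6
                continue
            xnp = camp[:2] / camp[2]
            xd = _distort(xnp[None, :], cam.distortion)[0]
            K = cam.intrinsics
            u = K[0, 0] * xd[0] + K[0, 1] * xd[1] + K[0, 2]
            v = K[1, 1] * xd[1] + K[1, 2]
            sw = math.sqrt(max(w, 1e-12))
            res[2 * i] = sw * (u - px[0])
            res[2 * i + 1] = sw * (v - px[1])
        return res

    if refine and reliable:
        sol = least_squares(residuals, point, method="lm", max_nfev=200)
        point = sol.x

    errs = []
    for cam, px in zip(cams, pixels):
        camp = cam.rotation @ point + cam.translation
        if camp[2] <= 0:
            errs.append(1e6)
            continue
        xd = _distort((camp[:2] / camp[2])[None, :], cam.distortion)[0]
        K = cam.intrinsics
        u = K[0, 0] * xd[0] + K[0, 1] * xd[1] + K[0, 2]
        v = K[1, 1] * xd[1] + K[1, 2]
        errs.append((u - px[0]) ** 2 + (v - px[1]) ** 2)
    rms = float(np.sqrt(np.mean(errs)))
    return TriangulationResult(np.asarray(point, float), rms, reliable)


def _triangulate_batch(pixels: np.ndarray, weights: np.ndarray,
                       cams: Sequence[CameraModel],
                       refine: bool, gn_iterations: int = 5
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized DLT + Gauss-Newton for distortion-free cameras.

    ``pixels``: (m, k, 2) for m samples seen by the same k cameras (all
    valid); ``weights``: (m, k).  Returns (points (m, 3), reliable (m,)).
    """
    m, k = pixels.shape[:2]
    xn = np.stack([pixel_to_normalized(cam, pixels[:, i, :])
                   for i, cam in enumerate(cams)], axis=1)  # (m, k, 2)
    P = np.stack([np.hstack([cam.rotation, cam.translation[:, None]])
                  for cam in cams])                          # (k, 3, 4)
    sw = np.sqrt(np.maximum(weights, 1e-12))
    A = np.empty((m, 2 * k, 4))
    for i in range(k):
        A[:, 2 * i] = sw[:, i, None] * (xn[:, i, 0, None] * P[i, 2] - P[i, 0])
        A[:, 2 * i + 1] = sw[:, i, None] * (xn[:, i, 1, None] * P[i, 2] - P[i, 1])
    _, s, vt = np.linalg.svd(A)
    X_h = vt[:, -1, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = s[:, 0] / s[:, -2]
    reliable = (np.abs(X_h[:, 3]) > 1e-15) & (cond <= _MAX_CONDITION)
    pts = X_h[:, :3] / np.where(np.abs(X_h[:, 3]) > 1e-15, X_h[:, 3], 1.0)[:, None]

    if refine:
        for _ in range(gn_iterations):
            JtJ = np.zeros((m, 3, 3))
            Jtr = np.zeros((m, 3))
            for i, cam in enumerate(cams):
                R, t, K = cam.rotation, cam.translation, cam.intrinsics
                c = pts @ R.T + t
                z = np.maximum(c[:, 2], 1e-9)
                u = K[0, 0] * c[:, 0] / z + K[0, 2]
                v = K[1, 1] * c[:, 1] / z + K[1, 2]
                r_u = u - pixels[:, i, 0]
                r_v = v - pixels[:, i, 1]
                Ju = K[0, 0] * (R[0][None, :] * z[:, None]
                                - c[:, 0, None] * R[2][None, :]) / (z ** 2)[:, None]
                Jv = K[1, 1] * (R[1][None, :] * z[:, None]
                                - c[:, 1, None] * R[2][None, :]) / (z ** 2)[:, None]
                w = weights[:, i, None]
                JtJ += w[..., None] * (Ju[:, :, None] * Ju[:, None, :]
                                       + Jv[:, :, None] * Jv[:, None, :])
                Jtr += w * (Ju * r_u[:, None] + Jv * r_v[:, None])
            ok = np.linalg.det(JtJ) > 1e-18
            step = np.zeros((m, 3))
            if ok.any():
                step[ok] = np.linalg.solve(JtJ[ok], Jtr[ok][..., None])[..., 0]
            pts = pts - step
    return pts, reliable


def triangulate_series(views: Sequence[KeypointSeries2D],
                       cameras: Mapping[str, CameraModel],
                       min_confidence: float = 0.0,
                       min_views: int = 2,
                       refine: bool = True,
                       vertical_axis: str = "Y",
                       skeleton: SkeletonDefinition | None = None) -> KeypointSeries3D:
    """Triangulate per-frame, per-keypoint 3D positions from multiple views.

    Only observations with confidence >= ``min_confidence`` participate; a
    sample is marked missing (not interpolated) when fewer than ``min_views``
    usable observations remain or the geometry is degenerate.
    """
    if len(views) < 2:
        raise InsufficientViewsError("need at least 2 views")
    fps = views[0].fps
    names = views[0].keypoints
    n_frames = views[0].n_frames
    for v in views[1:]:
        if abs(v.fps - fps) > 1e-9:
            raise DataError("views disagree on fps")
        if tuple(v.keypoints) != tuple(names):
            raise DataError("views disagree on keypoint names")
        if v.n_frames != n_frames:
            raise DataError("views disagree on frame count")

    view_cams = []
    for v in views:
        try:
            view_cams.append(cameras[v.camera_id])
        except KeyError:
            raise DataError(f"no calibration for camera {v.camera_id!r}") from None

    n_kp = len(names)
    xyz = np.full((n_frames, n_kp, 3), np.nan)
    missing = np.ones((n_frames, n_kp), dtype=bool)

    conf = np.stack([np.where(np.isnan(v.data[..., 2]), 1.0, v.data[..., 2])
                     for v in views])                       # (V, frames, K)
    usable = np.stack([~v.missing for v in views]) & (conf >= min_confidence)
    usable &= ~np.isnan(np.stack([v.data[..., 0] for v in views]))

    if not any(np.any(c.distortion) for c in view_cams):
        # vectorized path: group samples by their view-participation pattern
        flat_usable = usable.reshape(len(views), -1)        # (V, N)
        patterns = {}
        for idx in range(flat_usable.shape[1]):
            key = tuple(np.flatnonzero(flat_usable[:, idx]))
            if len(key) >= min_views:
                patterns.setdefault(key, []).append(idx)
        pix_all = np.stack([v.data[..., :2].reshape(-1, 2) for v in views])
        conf_flat = conf.reshape(len(views), -1)
        pts_flat = np.full((n_frames * n_kp, 3), np.nan)
        ok_flat = np.zeros(n_frames * n_kp, dtype=bool)
        for key, idxs in patterns.items():
            idxs = np.asarray(idxs)
            cams = [view_cams[i] for i in key]
            pixels = np.stack([pix_all[i][idxs] for i in key], axis=1)
            weights = np.stack([conf_flat[i][idxs] for i in key], axis=1)
            pts, reliable = _triangulate_batch(pixels, weights, cams, refine)
            pts_flat[idxs] = pts
            ok_flat[idxs] = reliable
        xyz = np.where(ok_flat[:, None], pts_flat, np.nan).reshape(n_frames, n_kp, 3)
        missing = ~ok_flat.reshape(n_frames, n_kp)
        return KeypointSeries3D(fps, tuple(names), xyz, missing, vertical_axis, skeleton)

    for f in range(n_frames):
        for k in range(n_kp):
            obs = []
            for i, v in enumerate(views):
                if not usable[i, f, k]:
                    continue
                u, vv = v.data[f, k, :2]
                obs.append(Observation2D(v.camera_id, (float(u), float(vv)),
                                         float(conf[i, f, k])))
            if len({o.camera_id for o in obs}) < min_views:
                continue
            try:
                result = triangulate(obs, cameras, refine=refine)
            except (DegenerateGeometryError, InsufficientViewsError):
                continue
            if result.reliable:
                xyz[f, k] = result.point
                missing[f, k] = False
    return KeypointSeries3D(fps, tuple(names), xyz, missing, vertical_axis, skeleton)


# ---------------------------------------------------------------------------
# Calibration file I/O
# ---------------------------------------------------------------------------

def _camera_to_dict(cam: CameraModel, units: str) -> dict:
    scale = 1000.0 if units == "mm" else 1.0
    return {
        "id": cam.camera_id,
        "image_size": [int(cam.image_size[0]), int(cam.image_size[1])],
        "K": [float(x) for x in cam.intrinsics.ravel()],
        "dist": [float(x) for x in cam.distortion],
        "R": [float(x) for x in cam.rotation.ravel()],
        "t": [float(x * scale) for x in cam.translation],
    }


def write_calibration(cameras: Sequence[CameraModel], path: str | Path,
                      units: str = "m") -> None:
    """Write a calibration file (JSON or YAML by extension)."""
    if units not in ("m", "mm"):
        raise ConfigError("units must be 'm' or 'mm'")
    payload = {"units": units, "cameras": [_camera_to_dict(c, units) for c in cameras]}
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if path.suffix.lower() in (".yaml", ".yml"):
            yaml.safe_dump(payload, fh, sort_keys=False)
        else:
            json.dump(payload, fh, indent=1)


def read_calibration(path: str | Path) -> dict[str, CameraModel]:
    """Read a calibration file; returns a camera_id -> CameraModel map with
    translations converted to meters."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        if path.suffix.lower() in (".yaml", ".yml"):
            payload = yaml.safe_load(fh)
        else:
            payload = json.load(fh)
    units = payload.get("units", "m")
    if units not in ("m", "mm"):
        raise DataError(f"{path}: units must be 'm' or 'mm'")
    scale = 1e-3 if units == "mm" else 1.0
    out: dict[str, CameraModel] = {}
    for entry in payload["cameras"]:
        cam = CameraModel(
            camera_id=str(entry["id"]),
            intrinsics=np.asarray(entry["K"], float).reshape(3, 3),
            rotation=np.asarray(entry["R"], float).reshape(3, 3),
            translation=np.asarray(entry["t"], float) * scale,
            distortion=np.asarray(entry.get("dist", [0, 0, 0, 0]), float),
            image_size=tuple(entry.get("image_size", (1292, 964))),
        )
        out[cam.camera_id] = cam
    return out
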