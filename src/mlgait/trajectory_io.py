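"""Skeleton definitions, keypoint trajectory containers, and file formats.

Trajectories are stored as dense ``frames x keypoints x coords`` arrays with
an explicit boolean missing mask; missing samples hold NaN coordinates.  CSV
is the on-disk format (sparse rows, ``#`` metadata header lines); a TRC
writer is provided for OpenSim interoperability.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mlgait.errors import ConfigError, DataError, MissingDataError

logger = logging.getLogger(__name__)

#: Anatomical roles a skeleton may bind to keypoint names.  ``head_top`` and
#: ``head_ref`` are the endpoints of the head segment used as the PCKh
#: reference length.
GAIT_ROLES = (
    "left_heel",
    "right_heel",
    "left_toe",
    "right_toe",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
    "pelvis_root",
    "head_top",
    "head_ref",
)

_AXES = {"X": 0, "Y": 1, "Z": 2}


@dataclass(frozen=True)
class SkeletonDefinition:
    """Named, ordered keypoint set with laterality tags, bones, and role bindings."""

    name: str
    keypoints: tuple[str, ...]
    laterality: tuple[str, ...]  # "left" | "right" | "center", parallel to keypoints
    bones: tuple[tuple[str, str], ...] = ()
    roles: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.keypoints)) != len(self.keypoints):
            raise ConfigError(f"skeleton {self.name!r}: duplicate keypoint names")
        if len(self.laterality) != len(self.keypoints):
            raise ConfigError(f"skeleton {self.name!r}: laterality length mismatch")
        bad = set(self.laterality) - {"left", "right", "center"}
        if bad:
            raise ConfigError(f"skeleton {self.name!r}: invalid laterality tags {bad}")
        names = set(self.keypoints)
        for a, b in self.bones:
            if a not in names or b not in names:
                raise ConfigError(f"skeleton {self.name!r}: bone ({a}, {b}) references unknown keypoint")
        for role, kp in self.roles.items():
            if role not in GAIT_ROLES:
                raise ConfigError(f"skeleton {self.name!r}: unknown role {role!r}")
            if kp not in names:
                raise ConfigError(f"skeleton {self.name!r}: role {role!r} bound to unknown keypoint {kp!r}")

    def index(self, keypoint: str) -> int:
        try:
            return self.keypoints.index(keypoint)
        except ValueError:
            raise DataError(f"keypoint {keypoint!r} not in skeleton {self.name!r}") from None

    def role_keypoint(self, role: str) -> str:
        """Keypoint name bound to ``role``; raises if the role is unbound."""
        if role not in GAIT_ROLES:
            raise ConfigError(f"unknown gait role {role!r}")
        try:
            return self.roles[role]
        except KeyError:
            raise DataError(
                f"skeleton {self.name!r} does not bind the {role!r} role required here"
            ) from None

    def role_index(self, role: str) -> int:
        return self.index(self.role_keypoint(role))


def h36m21_skeleton() -> SkeletonDefinition:
    """Default 21-keypoint whole-body skeleton (Human3.6M-style set extended
    with heels and toes)."""
    spec = [
        ("pelvis", "center"),
        ("belly", "center"),
        ("neck", "center"),
        ("nose", "center"),
        ("head", "center"),
        ("left_shoulder", "left"),
        ("left_elbow", "left"),
        ("left_wrist", "left"),
        ("right_shoulder", "right"),
        ("right_elbow", "right"),
        ("right_wrist", "right"),
        ("left_hip", "left"),
        ("left_knee", "left"),
        ("left_ankle", "left"),
        ("left_heel", "left"),
        ("left_toe", "left"),
        ("right_hip", "right"),
        ("right_knee", "right"),
        ("right_ankle", "right"),
        ("right_heel", "right"),
        ("right_toe", "right"),
    ]
    bones = (
        ("pelvis", "belly"), ("belly", "neck"), ("neck", "nose"), ("neck", "head"),
        ("neck", "left_shoulder"), ("left_shoulder", "left_elbow"), ("left_elbow", "left_wrist"),
        ("neck", "right_shoulder"), ("right_shoulder", "right_elbow"), ("right_elbow", "right_wrist"),
        ("pelvis", "left_hip"), ("left_hip", "left_knee"), ("left_knee", "left_ankle"),
        ("left_ankle", "left_heel"), ("left_heel", "left_toe"),
        ("pelvis", "right_hip"), ("right_hip", "right_knee"), ("right_knee", "right_ankle"),
        ("right_ankle", "right_heel"), ("right_heel", "right_toe"),
    )
    roles = {
        "left_heel": "left_heel", "right_heel": "right_heel",
        "left_toe": "left_toe", "right_toe": "right_toe",
        "left_hip": "left_hip", "right_hip": "right_hip",
        "left_knee": "left_knee", "right_knee": "right_knee",
        "left_ankle": "left_ankle", "right_ankle": "right_ankle",
        "pelvis_root": "pelvis", "head_top": "head", "head_ref": "nose",
    }
    return SkeletonDefinition(
        name="h36m21",
        keypoints=tuple(n for n, _ in spec),
        laterality=tuple(t for _, t in spec),
        bones=bones,
        roles=roles,
    )


def davis22_skeleton() -> SkeletonDefinition:
    """22-marker lower-body-centric marker set (Davis protocol placements).

    No heel markers exist in this protocol, so heel roles stay unbound; users
    can rebind roles for their own marker-to-role mapping.
    """
    bilateral = [
        "acromion", "asis", "greater_trochanter", "thigh_bar",
        "lateral_epicondyle", "fibula_head", "shank_bar", "lateral_malleolus",
        "first_metatarsal", "fifth_metatarsal",
    ]
    names: list[str] = ["c7", "sacrum"]
    tags: list[str] = ["center", "center"]
    for side in ("left", "right"):
        for m in bilateral:
            names.append(f"{side}_{m}")
            tags.append(side)
    roles = {
        "pelvis_root": "sacrum",
        "head_top": "c7",  # best available upper landmark; not a true head segment
        "head_ref": "sacrum",
        "left_hip": "left_greater_trochanter", "right_hip": "right_greater_trochanter",
        "left_knee": "left_lateral_epicondyle", "right_knee": "right_lateral_epicondyle",
        "left_ankle": "left_lateral_malleolus", "right_ankle": "right_lateral_malleolus",
        "left_toe": "left_first_metatarsal", "right_toe": "right_first_metatarsal",
    }
    return SkeletonDefinition(
        name="davis22", keypoints=tuple(names), laterality=tuple(tags), roles=roles
    )


_BUILTIN_SKELETONS = {"h36m21": h36m21_skeleton, "davis22": davis22_skeleton}


def get_skeleton(name: str) -> SkeletonDefinition:
    try:
        return _BUILTIN_SKELETONS[name]()
    except KeyError:
        raise ConfigError(f"unknown skeleton {name!r}; built-ins: {sorted(_BUILTIN_SKELETONS)}") from None


@dataclass
class KeypointSeries2D:
    """Per-camera 2D keypoint trajectories with confidences.

    ``data`` has shape ``(frames, n_keypoints, 3)`` holding (u, v, confidence);
    ``missing`` has shape ``(frames, n_keypoints)``.
    """

    camera_id: str
    fps: float
    keypoints: tuple[str, ...]
    data: np.ndarray
    missing: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.fps <= 0:
            raise ConfigError("fps must be positive")
        if self.data.ndim != 3 or self.data.shape[2] != 3:
            raise DataError(f"2D data must be (frames, keypoints, 3); got {self.data.shape}")
        if self.data.shape[1] != len(self.keypoints):
            raise DataError("keypoint axis does not match keypoint names")
        if self.missing.shape != self.data.shape[:2]:
            raise DataError("missing mask shape mismatch")
        conf = self.data[~self.missing][:, 2]
        if conf.size and (np.nanmin(conf) < 0 or np.nanmax(conf) > 1):
            raise DataError("confidences must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def copy(self) -> "KeypointSeries2D":
        return KeypointSeries2D(self.camera_id, self.fps, self.keypoints,
                                self.data.copy(), self.missing.copy())


@dataclass
class KeypointSeries3D:
    """3D keypoint trajectories in meters.

    ``xyz`` has shape ``(frames, n_keypoints, 3)``; missing samples hold NaN
    and are flagged in ``missing``.
    """

    fps: float
    keypoints: tuple[str, ...]
    xyz: np.ndarray
    missing: np.ndarray
    vertical_axis: str = "Y"
    skeleton: SkeletonDefinition | None = None

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.fps <= 0:
            raise ConfigError("fps must be positive")
        if self.xyz.ndim != 3 or self.xyz.shape[2] != 3:
            raise DataError(f"3D data must be (frames, keypoints, 3); got {self.xyz.shape}")
        if self.xyz.shape[1] != len(self.keypoints):
            raise DataError("keypoint axis does not match keypoint names")
        if self.missing.shape != self.xyz.shape[:2]:
            raise DataError("missing mask shape mismatch")
        if self.vertical_axis not in _AXES:
            raise ConfigError(f"vertical_axis must be one of X/Y/Z, got {self.vertical_axis!r}")
        if self.skeleton is not None and tuple(self.skeleton.keypoints) != tuple(self.keypoints):
            raise DataError("skeleton keypoint set does not match series keypoints")

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    @property
    def vertical_index(self) -> int:
        return _AXES[self.vertical_axis]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    def index(self, keypoint: str) -> int:
        try:
            return self.keypoints.index(keypoint)
        except ValueError:
            raise DataError(f"keypoint {keypoint!r} not in series") from None

    def trajectory(self, keypoint: str) -> np.ndarray:
        """(frames, 3) view of one keypoint's trajectory."""
        return self.xyz[:, self.index(keypoint), :]

    def role_trajectory(self, role: str) -> np.ndarray:
        if self.skeleton is None:
            raise DataError("series has no skeleton; cannot resolve gait roles")
        return self.trajectory(self.skeleton.role_keypoint(role))

    def up_vector(self) -> np.ndarray:
        up = np.zeros(3)
        up[self.vertical_index] = 1.0
        return up

    def copy(self) -> "KeypointSeries3D":
        return KeypointSeries3D(self.fps, self.keypoints, self.xyz.copy(),
                                self.missing.copy(), self.vertical_axis, self.skeleton)

    def with_xyz(self, xyz: np.ndarray, missing: np.ndarray | None = None) -> "KeypointSeries3D":
        return KeypointSeries3D(self.fps, self.keypoints, np.asarray(xyz, float),
                                self.missing.copy() if missing is None else np.asarray(missing, bool),
                                self.vertical_axis, self.skeleton)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _read_csv_with_meta(path: str | Path) -> tuple[dict[str, str], pd.DataFrame]:
    meta: dict[str, str] = {}
    body = io.StringIO()
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if "=" in stripped:
                    key, _, value = stripped.partition("=")
                    meta[key.strip()] = value.strip()
            else:
                body.write(line)
    body.seek(0)
    df = pd.read_csv(body, float_precision="round_trip")
    return meta, df


def _require_meta(meta: dict[str, str], key: str, path: str | Path) -> str:
    if key not in meta:
        raise DataError(f"{path}: missing required metadata field '# {key}='")
    return meta[key]


def _resolve_skeleton(meta: dict[str, str],
                      skeleton: SkeletonDefinition | None) -> SkeletonDefinition | None:
    if skeleton is not None:
        return skeleton
    if "skeleton" in meta:
        return get_skeleton(meta["skeleton"])
    return None


def _check_frames(frames: np.ndarray, path: str | Path) -> None:
    if frames.size and np.any(frames < 0):
        raise DataError(f"{path}: negative frame indices")
    # rows must be grouped by non-decreasing frame
    if frames.size and np.any(np.diff(frames) < 0):
        raise DataError(f"{path}: frame column is not monotonically non-decreasing")


def read_keypoints_2d(path: str | Path,
                      skeleton: SkeletonDefinition | None = None) -> KeypointSeries2D:
    """Read a sparse 2D keypoint CSV (columns frame,keypoint,u,v,confidence)."""
    meta, df = _read_csv_with_meta(path)
    fps = float(_require_meta(meta, "fps", path))
    camera_id = _require_meta(meta, "camera_id", path)
    skel = _resolve_skeleton(meta, skeleton)

    required = {"frame", "keypoint", "u", "v", "confidence"}
    if not required.issubset(df.columns):
        raise DataError(f"{path}: expected columns {sorted(required)}")
    frames = df["frame"].to_numpy(int)
    _check_frames(frames, path)

    if skel is not None:
        names = tuple(skel.keypoints)
    else:
        names = tuple(dict.fromkeys(df["keypoint"]))
    name_to_idx = {n: i for i, n in enumerate(names)}
    unknown = set(df["keypoint"]) - set(names)
    if unknown:
        raise DataError(f"{path}: unknown keypoints {sorted(unknown)}")

    n_frames = int(meta.get("frames", frames.max() + 1 if frames.size else 0))
    data = np.full((n_frames, len(names), 3), np.nan)
    missing = np.ones((n_frames, len(names)), dtype=bool)
    ki = df["keypoint"].map(name_to_idx).to_numpy(int)
    data[frames, ki, 0] = df["u"].to_numpy(float)
    data[frames, ki, 1] = df["v"].to_numpy(float)
    data[frames, ki, 2] = df["confidence"].to_numpy(float)
    missing[frames, ki] = False
    return KeypointSeries2D(camera_id, fps, names, data, missing)


def write_keypoints_2d(series: KeypointSeries2D, path: str | Path) -> None:
    rows = []
    for f in range(series.n_frames):
        for k, name in enumerate(series.keypoints):
            if not series.missing[f, k]:
                u, v, c = series.data[f, k]
                rows.append((f, name, repr(float(u)), repr(float(v)), repr(float(c))))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# camera_id={series.camera_id}\n")
        fh.write(f"# fps={series.fps!r}\n")
        fh.write(f"# frames={series.n_frames}\n")
        fh.write("frame,keypoint,u,v,confidence\n")
        for row in rows:
            fh.write(",".join(str(x) for x in row) + "\n")


def read_keypoints_3d(path: str | Path,
                      skeleton: SkeletonDefinition | None = None) -> KeypointSeries3D:
    """Read a sparse 3D keypoint CSV (columns frame,keypoint,x,y,z).

    Values declared ``# units=mm`` are converted to meters on read.
    """
    meta, df = _read_csv_with_meta(path)
    fps = float(_require_meta(meta, "fps", path))
    units = meta.get("units", "m")
    if units not in ("m", "mm"):
        raise DataError(f"{path}: units must be 'm' or 'mm', got {units!r}")
    vertical_axis = meta.get("vertical_axis", "Y")
    skel = _resolve_skeleton(meta, skeleton)

    required = {"frame", "keypoint", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise DataError(f"{path}: expected columns {sorted(required)}")
    frames = df["frame"].to_numpy(int)
    _check_frames(frames, path)

    if skel is not None:
        names = tuple(skel.keypoints)
        unknown = set(df["keypoint"]) - set(names)
        if unknown:
            raise DataError(f"{path}: unknown keypoints {sorted(unknown)}")
    else:
        names = tuple(dict.fromkeys(df["keypoint"]))
    name_to_idx = {n: i for i, n in enumerate(names)}

    n_frames = int(meta.get("frames", frames.max() + 1 if frames.size else 0))
    xyz = np.full((n_frames, len(names), 3), np.nan)
    missing = np.ones((n_frames, len(names)), dtype=bool)
    ki = df["keypoint"].map(name_to_idx).to_numpy(int)
    xyz[frames, ki, 0] = df["x"].to_numpy(float)
    xyz[frames, ki, 1] = df["y"].to_numpy(float)
    xyz[frames, ki, 2] = df["z"].to_numpy(float)
    missing[frames, ki] = False
    if units == "mm":
        logger.info("%s: converting mm to m on read", path)
        xyz /= 1000.0
    return KeypointSeries3D(fps, names, xyz, missing, vertical_axis, skel)


def write_keypoints_3d(series: KeypointSeries3D, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# fps={series.fps!r}\n")
        fh.write("# units=m\n")
        fh.write(f"# vertical_axis={series.vertical_axis}\n")
        fh.write(f"# frames={series.n_frames}\n")
        if series.skeleton is not None and series.skeleton.name in _BUILTIN_SKELETONS:
            fh.write(f"# skeleton={series.skeleton.name}\n")
        fh.write("frame,keypoint,x,y,z\n")
        for f in range(series.n_frames):
            for k, name in enumerate(series.keypoints):
                if not series.missing[f, k]:
                    x, y, z = series.xyz[f, k]
                    fh.write(f"{f},{name},{float(x)!r},{float(y)!r},{float(z)!r}\n")


# ---------------------------------------------------------------------------
# TRC export
# ---------------------------------------------------------------------------

def write_trc(series: KeypointSeries3D, path: str | Path) -> None:
    """Write a tab-delimited TRC marker file (OpenSim-compatible).

    The series must be gap-free; interpolate first.
    """
    if series.missing.any():
        raise MissingDataError("TRC export requires a gap-free series; run gap interpolation first")
    path = Path(path)
    n_frames = series.n_frames
    n_markers = len(series.keypoints)
    rate = series.fps
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path.name}\n")
        fh.write("DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
                 "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n")
        fh.write(f"{rate:g}\t{rate:g}\t{n_frames}\t{n_markers}\tm\t{rate:g}\t1\t{n_frames}\n")
        fh.write("Frame#\tTime\t" + "\t\t\t".join(series.keypoints) + "\t\t\n")
        comps = "\t".join(f"X{i}\tY{i}\tZ{i}" for i in range(1, n_markers + 1))
        fh.write("\t\t" + comps + "\n")
        fh.write("\n")
        for f in range(n_frames):
            t = f / rate
            vals = "\t".join(f"{v:.8f}" for v in series.xyz[f].ravel())
            fh.write(f"{f + 1}\t{t:.8f}\t{vals}\n")


def rotate_world(series: KeypointSeries3D, rotation: np.ndarray,
                 translation: Sequence[float] = (0.0, 0.0, 0.0),
                 vertical_axis: str | None = None) -> KeypointSeries3D:
    """Apply a rigid world transform ``x -> R x + t`` to every sample."""
    rotation = np.asarray(rotation, float)
    xyz = series.xyz @ rotation.T + np.asarray(translation, float)
    out = series.with_xyz(xyz)
    if vertical_axis is not None:
        out = replace(out, vertical_axis=vertical_axis)
    return out
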