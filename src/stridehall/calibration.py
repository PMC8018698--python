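"""Sensor intrinsics, pinhole projection, and the room coordinate system.

A smart-hallway rig is a set of pinhole depth sensors with known intrinsics
(``fx, fy, cx, cy`` in pixels) and extrinsics (rigid transforms into a common
frame).  The room coordinate system (RCS) is a floor-anchored right-handed
frame built from three key points identified on a chessboard lying on the
floor: x points medial-lateral (ML), y along the walkway (anterior-posterior,
AP), z up.  All lengths are millimetres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SensorIntrinsics",
    "RigidTransform",
    "RoomCoordinateSystem",
    "project_point",
    "project_points",
    "deproject_pixel",
    "deproject_grid",
    "robust_keypoint",
    "build_room_transform",
    "load_calibration",
    "save_calibration",
]


@dataclass(frozen=True)
class SensorIntrinsics:
    """Pinhole intrinsics of one depth sensor (pixels)."""

    fx: float
    fy: float
    cx: float
    cy: float
    rows: int
    cols: int

    def __post_init__(self) -> None:
        if not (self.fx > 0 and self.fy > 0):
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.cols and 0 <= self.cy < self.rows):
            raise ValueError("principal point must lie inside the image")

    def halved(self) -> "SensorIntrinsics":
        """Intrinsics after 2x2 down-sampling of the image grid."""
        return SensorIntrinsics(
            self.fx / 2, self.fy / 2, self.cx / 2, self.cy / 2,
            self.rows // 2, self.cols // 2,
        )


@dataclass(frozen=True)
class RigidTransform:
    """A 4x4 homogeneous rigid transform (rotation + translation in mm)."""

    matrix: np.ndarray

    ORTHONORMALITY_TOL = 1e-6

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("rigid transform must be 4x4")
        object.__setattr__(self, "matrix", m)
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=1e-12):
            raise ValueError("last row must be (0, 0, 0, 1)")
        r = m[:3, :3]
        defect = np.abs(r @ r.T - np.eye(3)).max()
        if defect > self.ORTHONORMALITY_TOL:
            raise ValueError(
                f"rotation block is not orthonormal (defect {defect:.3g})"
            )
        if np.linalg.det(r) < 0:
            raise ValueError("rotation block must have determinant +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation_translation(cls, rotation: np.ndarray, translation: np.ndarray) -> "RigidTransform":
        m = np.eye(4)
        m[:3, :3] = rotation
        m[:3, 3] = translation
        return cls(m)

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def inverse(self) -> "RigidTransform":
        r = self.rotation.T
        return RigidTransform.from_rotation_translation(r, -r @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self @ other)(p) = self(other(p))."""
        return RigidTransform(self.matrix @ other.matrix)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (N, 3) array (or a single 3-vector) of points."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        out = p @ self.rotation.T + self.translation
        return out[0] if np.ndim(points) == 1 else out


def project_point(point, intr: SensorIntrinsics) -> tuple[int, int]:
    """Project a 3-D point in the camera frame to its (row, col) pixel.

    ``row = floor(y*fy/z + cy)``, ``col = floor(x*fx/z + cx)``.  Raises on
    non-positive depth.
    """
    x, y, z = np.asarray(point, dtype=float)
    if z <= 0:
        raise ValueError("cannot project a point with non-positive depth")
    # the tiny epsilon keeps exact-integer pixel coordinates (e.g. from a
    # deproject round trip) off the floor() discontinuity
    row = int(np.floor(y * intr.fy / z + intr.cy + 1e-9))
    col = int(np.floor(x * intr.fx / z + intr.cx + 1e-9))
    return row, col


def project_points(points: np.ndarray, intr: SensorIntrinsics) -> np.ndarray:
    """Vectorised :func:`project_point`; returns an (N, 2) int array of (row, col)."""
    p = np.asarray(points, dtype=float)
    z = p[:, 2]
    if np.any(z <= 0):
        raise ValueError("cannot project points with non-positive depth")
    rows = np.floor(p[:, 1] * intr.fy / z + intr.cy + 1e-9).astype(int)
    cols = np.floor(p[:, 0] * intr.fx / z + intr.cx + 1e-9).astype(int)
    return np.stack([rows, cols], axis=1)


def deproject_pixel(row: float, col: float, depth: float, intr: SensorIntrinsics) -> np.ndarray:
    """Back-project one pixel at a given depth (mm) to a camera-frame 3-D point."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    x = (col - intr.cx) * depth / intr.fx
    y = (row - intr.cy) * depth / intr.fy
    return np.array([x, y, depth], dtype=float)


def deproject_grid(depth: np.ndarray, intr: SensorIntrinsics, valid: np.ndarray | None = None) -> np.ndarray:
    """Back-project every valid cell of a depth image to camera-frame points.

    ``valid`` is a boolean mask of cells to deproject (default: depth > 0).
    Returns an (N, 3) float array.
    """
    d = np.asarray(depth, dtype=float)
    if valid is None:
        valid = d > 0
    rows, cols = np.nonzero(valid)
    z = d[rows, cols]
    x = (cols - intr.cx) * z / intr.fx
    y = (rows - intr.cy) * z / intr.fy
    return np.stack([x, y, z], axis=1)


def robust_keypoint(samples: np.ndarray) -> np.ndarray:
    """Average the middle 50 order statistics of each coordinate independently.

    The chessboard key points are sampled over (at least) 100 frames; each of
    x, y, z is sorted separately and the 50 central values are averaged,
    which gives gross outliers in either tail zero influence.
    """
    s = np.asarray(samples, dtype=float)
    if s.ndim != 2 or s.shape[1] != 3:
        raise ValueError("samples must be an (N, 3) array")
    n = s.shape[0]
    if n < 100:
        raise ValueError(f"need at least 100 samples, got {n}")
    lo = (n - 50) // 2
    srt = np.sort(s, axis=0)
    return srt[lo:lo + 50].mean(axis=0)


def build_room_transform(k1, k2, k3, *, reorthogonalize: bool = True) -> RigidTransform:
    """Room transform from three floor key points.

    The room axes are x from k2 to k3, y from k2 to k1, z their cross
    product; the transform returned maps first-sensor coordinates into the
    room frame (the inverse of the assembled pose matrix), so k2 maps to the
    origin and k3 onto the +x ray.

    With ``reorthogonalize`` (default) y is replaced by z x x so the result
    satisfies the rigid-transform contract even when the measured axes are
    slightly non-orthogonal; with it off, a non-orthonormal measurement
    raises rather than being silently fixed.
    """
    k1 = np.asarray(k1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    k3 = np.asarray(k3, dtype=float)
    x = k3 - k2
    y = k1 - k2
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("key points are coincident")
    x = x / nx
    y = y / ny
    z = np.cross(x, y)
    nz = np.linalg.norm(z)
    if nz < 1e-9:
        raise ValueError("key points are collinear")
    if reorthogonalize:
        z = z / nz
        y = np.cross(z, x)
    pose = np.eye(4)
    pose[:3, 0] = x
    pose[:3, 1] = y
    pose[:3, 2] = z
    pose[:3, 3] = k2
    return RigidTransform(np.linalg.inv(pose))


@dataclass(frozen=True)
class RoomCoordinateSystem:
    """Three floor key points plus the transform they define."""

    k1: np.ndarray
    k2: np.ndarray
    k3: np.ndarray
    transform: RigidTransform = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.transform is None:
            object.__setattr__(self, "transform", build_room_transform(self.k1, self.k2, self.k3))
        if np.linalg.norm(self.transform.apply(self.k2)) > 1e-6:
            raise ValueError("room transform does not map k2 to the origin")


def save_calibration(path, intrinsics: dict[str, SensorIntrinsics], extrinsics: dict[str, RigidTransform], room: RigidTransform | None = None) -> None:
    """Write a calibration file: per-sensor intrinsics, extrinsics (row-major 16
    numbers, sensor -> first frame), and optionally the room transform."""
    doc = {
        "sensors": {
            sid: {
                "intrinsics": {
                    "fx": i.fx, "fy": i.fy, "cx": i.cx, "cy": i.cy,
                    "rows": i.rows, "cols": i.cols,
                },
                "extrinsics": extrinsics[sid].matrix.reshape(-1).tolist(),
            }
            for sid, i in intrinsics.items()
        },
    }
    if room is not None:
        doc["room_transform"] = room.matrix.reshape(-1).tolist()
    Path(path).write_text(json.dumps(doc, indent=2))


def load_calibration(path):
    """Inverse of :func:`save_calibration`.

    Returns ``(intrinsics, extrinsics, room_transform_or_None)``.
    """
    doc = json.loads(Path(path).read_text())
    intrinsics: dict[str, SensorIntrinsics] = {}
    extrinsics: dict[str, RigidTransform] = {}
    for sid, entry in doc["sensors"].items():
        i = entry["intrinsics"]
        intrinsics[sid] = SensorIntrinsics(i["fx"], i["fy"], i["cx"], i["cy"], i["rows"], i["cols"])
        extrinsics[sid] = RigidTransform(np.array(entry["extrinsics"], dtype=float).reshape(4, 4))
    room = None
    if "room_transform" in doc:
        room = RigidTransform(np.array(doc["room_transform"], dtype=float).reshape(4, 4))
    return intrinsics, extrinsics, room
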