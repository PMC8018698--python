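"""Point-cloud construction, fusion, and the filter chain.

Masked depth frames from each sensor are back-projected through the pinhole
model and transformed into the room frame; the merged cloud is then cleaned
by a statistical outlier filter (k=100 neighbours, 1 sigma), smoothed with
moving-least-squares quadric fitting (30 mm radius), and down-sampled on a
5 mm voxel grid anchored at the room origin.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
import warnings

import numpy as np
from scipy.spatial import cKDTree

from .calibration import RigidTransform, SensorIntrinsics, deproject_grid
from .depthimage import DEPTH_MAX_MM, DepthFrame

__all__ = [
    "PointCloud",
    "construct_cloud",
    "statistical_outlier_filter",
    "mls_smooth",
    "voxel_downsample",
    "filter_chain",
    "write_ply",
    "read_ply",
    "write_pcd",
    "read_pcd",
]


@dataclass(frozen=True)
class PointCloud:
    """An unordered (N, 3) set of points in mm, tagged with its frame."""

    points: np.ndarray
    frame: str = "room"
    timestamp: float | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if p.size and not np.isfinite(p).all():
            raise ValueError("point coordinates must be finite")
        object.__setattr__(self, "points", p)

    def __len__(self) -> int:
        return self.points.shape[0]

    def with_points(self, points: np.ndarray) -> "PointCloud":
        return replace(self, points=points)

    def transformed(self, t: RigidTransform, frame: str) -> "PointCloud":
        pts = t.apply(self.points) if len(self) else self.points
        return PointCloud(pts, frame, self.timestamp)

    def translated(self, offset) -> "PointCloud":
        return self.with_points(self.points + np.asarray(offset, dtype=float))


def construct_cloud(bs: DepthFrame, intr: SensorIntrinsics, to_room: RigidTransform) -> PointCloud:
    """Back-project every valid masked-depth cell into the room frame.

    Cells holding 0 (no data / filtered out) or the 5000 mm sentinel are
    skipped.  Point order is unspecified.
    """
    d = bs.depth
    valid = (d != 0) & (d != DEPTH_MAX_MM)
    pts = deproject_grid(d, intr, valid)
    if len(pts):
        pts = to_room.apply(pts)
    return PointCloud(pts, "room", bs.timestamp)


def merge_clouds(clouds) -> PointCloud:
    clouds = [c for c in clouds if len(c)]
    if not clouds:
        return PointCloud(np.empty((0, 3)))
    frame = clouds[0].frame
    ts = clouds[0].timestamp
    return PointCloud(np.vstack([c.points for c in clouds]), frame, ts)


def statistical_outlier_filter(pc: PointCloud, k: int = 100, n_sigma: float = 1.0) -> PointCloud:
    """Remove points whose mean k-NN distance is an outlier.

    For each point the mean distance to its k nearest neighbours is
    computed; points where that statistic exceeds the global
    ``mean + n_sigma * std`` are dropped.  A cloud with N <= k points is
    passed through with a warning.  Zero variance (e.g. a perfect lattice)
    removes nothing.
    """
    n = len(pc)
    if n <= k:
        warnings.warn("statistical_outlier_filter: cloud smaller than k, passing through")
        return pc
    tree = cKDTree(pc.points)
    dist, _ = tree.query(pc.points, k=k + 1)
    mean_d = dist[:, 1:].mean(axis=1)
    std = mean_d.std()
    if std <= 1e-9 * max(mean_d.mean(), 1.0):
        return pc  # statistically identical points: nothing to remove
    return pc.with_points(pc.points[mean_d <= mean_d.mean() + n_sigma * std])


def _batched_quadric_fit(points: np.ndarray, query: np.ndarray, idx_pad: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted quadric MLS projection for every point at once.

    ``idx_pad`` is an (N, m) padded neighbour-index array and ``w`` the
    matching weights (0 for padding).  Each point gets a local frame from
    its weighted neighbourhood PCA; a quadratic height field
    z' = c0 + c1 x' + c2 y' + c3 x'^2 + c4 x'y' + c5 y'^2 is fitted and the
    point is moved onto it along the local normal.
    """
    nb = points[idx_pad]                          # (N, m, 3)
    wsum = w.sum(axis=1, keepdims=True)           # (N, 1)
    ctr = (nb * w[..., None]).sum(axis=1) / wsum  # (N, 3)
    d = nb - ctr[:, None, :]
    cov = np.einsum("nmi,nmj,nm->nij", d, d, w) / wsum[..., None]
    evals, evecs = np.linalg.eigh(cov)            # ascending; evecs[:,:,0] = normal
    normal = evecs[:, :, 0]
    e1 = evecs[:, :, 2]
    e2 = evecs[:, :, 1]
    # local coordinates of neighbours and of the query point
    u = np.einsum("nmi,ni->nm", d, e1)
    v = np.einsum("nmi,ni->nm", d, e2)
    h = np.einsum("nmi,ni->nm", d, normal)
    dq = query - ctr
    uq = np.einsum("ni,ni->n", dq, e1)
    vq = np.einsum("ni,ni->n", dq, e2)
    ones = np.ones_like(u)
    A = np.stack([ones, u, v, u * u, u * v, v * v], axis=-1)  # (N, m, 6)
    Aw = A * w[..., None]
    ata = np.einsum("nmi,nmj->nij", Aw, A)
    atb = np.einsum("nmi,nm->ni", Aw, h)
    # ridge for numerically singular neighbourhoods (e.g. collinear)
    ata += 1e-9 * np.eye(6)
    coef = np.linalg.solve(ata, atb[..., None])[..., 0]
    hq = (
        coef[:, 0] + coef[:, 1] * uq + coef[:, 2] * vq
        + coef[:, 3] * uq * uq + coef[:, 4] * uq * vq + coef[:, 5] * vq * vq
    )
    return ctr + e1 * uq[:, None] + e2 * vq[:, None] + normal * hq[:, None]


def mls_smooth(pc: PointCloud, radius: float = 30.0, order: int = 2, max_neighbors: int = 32) -> PointCloud:
    """Moving-least-squares smoothing with a local order-2 polynomial.

    Each point is projected onto a quadric fitted (Gaussian-weighted,
    bandwidth radius/3) to its neighbours within ``radius`` mm.  Points with
    fewer than 6 neighbours — not enough to determine a quadratic — are left
    unchanged.  Neighbourhoods are capped at the ``max_neighbors`` nearest
    points for bounded cost.
    """
    if order != 2:
        raise NotImplementedError("only order-2 MLS is implemented")
    n = len(pc)
    if n == 0:
        return pc
    pts = pc.points
    tree = cKDTree(pts)
    m = min(max_neighbors, n)
    dist, idx = tree.query(pts, k=m, distance_upper_bound=radius)
    in_r = np.isfinite(dist)
    counts = in_r.sum(axis=1)
    movable = counts >= 6
    out = pts.copy()
    if movable.any():
        idx_pad = np.where(in_r, idx, 0)[movable]
        bw = radius / 3.0
        w = np.where(in_r, np.exp(-(np.where(in_r, dist, 0) ** 2) / (2 * bw * bw)), 0.0)[movable]
        out[movable] = _batched_quadric_fit(pts, pts[movable], idx_pad, w)
    return pc.with_points(out)


def voxel_downsample(pc: PointCloud, voxel: float = 5.0) -> PointCloud:
    """Replace the points of each occupied voxel by their centroid.

    The grid is anchored at the room origin (bucket = floor(coord/voxel)),
    so the result is deterministic and reproducible under whole-mm
    translations of the scene by voxel multiples.
    """
    if len(pc) == 0:
        return pc
    keys = np.floor(pc.points / voxel).astype(np.int64)
    _, inv, counts = np.unique(keys, axis=0, return_inverse=True, return_counts=True)
    sums = np.zeros((counts.size, 3))
    np.add.at(sums, inv, pc.points)
    return pc.with_points(sums / counts[:, None])


def filter_chain(pc: PointCloud, k: int = 100, n_sigma: float = 1.0,
                 mls_radius: float = 30.0, voxel: float = 5.0) -> PointCloud:
    """The full cleanup chain: outlier removal, MLS smoothing, voxel grid."""
    pc = statistical_outlier_filter(pc, k=k, n_sigma=n_sigma)
    pc = mls_smooth(pc, radius=mls_radius)
    return voxel_downsample(pc, voxel=voxel)


# ---------------------------------------------------------------------------
# file I/O


def write_ply(path, pc: PointCloud, binary: bool = False) -> None:
    import trimesh

    t = trimesh.PointCloud(pc.points)
    Path(path).write_bytes(t.export(file_type="ply", encoding="binary" if binary else "ascii"))


def read_ply(path, frame: str = "room") -> PointCloud:
    import trimesh

    t = trimesh.load(str(path), file_type="ply", process=False)
    return PointCloud(np.asarray(t.vertices, dtype=float), frame)


def save_cloud_sequence(out_dir, clouds, prefix: str = "frame") -> None:
    """Write a per-frame cloud sequence as numbered PLY files plus a JSON
    manifest (index, filename, timestamp, point count)."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, pc in enumerate(clouds):
        name = f"{prefix}_{i:05d}.ply"
        write_ply(out / name, pc)
        manifest.append({"index": i, "file": name, "timestamp": pc.timestamp,
                         "n_points": len(pc), "frame": pc.frame})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_cloud_sequence(in_dir) -> list[PointCloud]:
    """Inverse of :func:`save_cloud_sequence`."""
    import json

    root = Path(in_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    out = []
    for entry in sorted(manifest, key=lambda e: e["index"]):
        pc = read_ply(root / entry["file"], frame=entry.get("frame", "room"))
        out.append(PointCloud(pc.points, pc.frame, entry.get("timestamp")))
    return out


def write_pcd(path, pc: PointCloud) -> None:
    """Minimal ASCII PCD v0.7 writer (x y z, float32)."""
    n = len(pc)
    header = (
        "# .PCD v0.7 - Point Cloud Data file format\n"
        "VERSION 0.7\nFIELDS x y z\nSIZE 4 4 4\nTYPE F F F\nCOUNT 1 1 1\n"
        f"WIDTH {n}\nHEIGHT 1\nVIEWPOINT 0 0 0 1 0 0 0\nPOINTS {n}\nDATA ascii\n"
    )
    body = "\n".join(" ".join(f"{v:.6f}" for v in p) for p in pc.points)
    Path(path).write_text(header + body + ("\n" if n else ""))


def read_pcd(path, frame: str = "room") -> PointCloud:
    """Minimal ASCII PCD reader matching :func:`write_pcd`."""
    lines = Path(path).read_text().splitlines()
    data_at = next(i for i, ln in enumerate(lines) if ln.startswith("DATA"))
    if "ascii" not in lines[data_at]:
        raise ValueError("only ASCII PCD files are supported")
    pts = [tuple(map(float, ln.split()[:3])) for ln in lines[data_at + 1:] if ln.strip()]
    return PointCloud(np.array(pts, dtype=float).reshape(-1, 3), frame)
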