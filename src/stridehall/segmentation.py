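"""Lower-leg cropping and left/right leg segmentation.

The fused room-frame cloud is cropped below 700 mm (the shank and foot are
always in that band), split into clusters by Euclidean clustering with a
50 mm tolerance, and each frame is classified as two legs, a single leg, or
two legs merged into one cluster.  Merged frames are split by comparing with
a recent reference frame: points near the reference stance leg are the
non-moving leg, the rest the swinging leg.  Average leg dimensions — used to
validate cluster volumes — come from an oriented bounding box (OBB) around
each leg over 40 calibration observations with a centre-20 trimmed mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from .pointcloud import PointCloud, statistical_outlier_filter

__all__ = [
    "OrientedBoundingBox",
    "LegDimensions",
    "FrameCategory",
    "FrameSegmentation",
    "crop_lower",
    "euclidean_cluster",
    "oriented_bounding_box",
    "classify_frame",
    "average_leg_dimensions",
    "moving_points_segmentation",
    "find_reference_frame",
]

CROP_HEIGHT_MM = 700.0
CLUSTER_TOLERANCE_MM = 50.0
MIN_CLUSTER_POINTS = 1000
MATCH_RADIUS_MM = 20.0
MOVING_SPLIT_MIN_FRACTION = 0.30
REFERENCE_MAX_AGE_S = 0.5


def crop_lower(pc: PointCloud, height: float = CROP_HEIGHT_MM) -> PointCloud:
    """Keep points strictly below ``height`` mm above the floor."""
    return pc.with_points(pc.points[pc.points[:, 2] < height])


def euclidean_cluster(pc: PointCloud, tolerance: float = CLUSTER_TOLERANCE_MM) -> list[PointCloud]:
    """Partition a cloud into Euclidean clusters.

    Two points share a cluster iff they are connected by a chain of hops of
    at most ``tolerance`` mm.  Clusters are returned sorted by size,
    descending (stable for equal sizes).
    """
    n = len(pc)
    if n == 0:
        return []
    tree = cKDTree(pc.points)
    pairs = tree.query_pairs(tolerance, output_type="ndarray")
    graph = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    ncomp, labels = sparse.csgraph.connected_components(graph, directed=False)
    order = np.argsort(-np.bincount(labels, minlength=ncomp), kind="stable")
    return [pc.with_points(pc.points[labels == lab]) for lab in order]


@dataclass(frozen=True)
class OrientedBoundingBox:
    """A PCA-aligned box: centre, orthonormal axes, and extents along them."""

    center: np.ndarray
    rotation: np.ndarray  # columns are the box axes, descending extent of variance
    dims: np.ndarray      # extent along each axis, mm

    @property
    def volume(self) -> float:
        return float(np.prod(self.dims))

    def corners(self) -> np.ndarray:
        """The 8 box corners, (8, 3)."""
        signs = np.array([[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)], dtype=float)
        return self.center + (signs * (self.dims / 2)) @ self.rotation.T

    def contains(self, points: np.ndarray, tol: float = 1e-6) -> np.ndarray:
        local = (np.asarray(points) - self.center) @ self.rotation
        return np.all(np.abs(local) <= self.dims / 2 + tol, axis=1)


def _fix_axis_signs(axes: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector signs: each axis points towards the
    (+x, +y, +z) half-space in priority order; the last axis is then flipped
    if needed to keep determinant +1."""
    axes = axes.copy()
    for j in range(3):
        v = axes[:, j]
        for c in range(3):
            if abs(v[c]) > 1e-12:
                if v[c] < 0:
                    axes[:, j] = -v
                break
    if np.linalg.det(axes) < 0:
        axes[:, 2] = -axes[:, 2]
    return axes


def oriented_bounding_box(pc: PointCloud | np.ndarray) -> OrientedBoundingBox:
    """Fit a PCA oriented bounding box around a cloud.

    Axes are the eigenvectors of the centred covariance (descending
    eigenvalue); the extent along each axis spans the projected min/max, and
    the box centre is the midpoint of those extents so the box contains
    every input point.
    """
    pts = pc.points if isinstance(pc, PointCloud) else np.asarray(pc, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points for an oriented bounding box")
    centroid = pts.mean(axis=0)
    d = pts - centroid
    cov = d.T @ d / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] <= 1e-12 * max(evals[2], 1.0):
        raise ValueError("degenerate (collinear or coincident) point set")
    axes = _fix_axis_signs(evecs[:, ::-1])
    proj = d @ axes
    lo, hi = proj.min(axis=0), proj.max(axis=0)
    center = centroid + axes @ ((lo + hi) / 2)
    return OrientedBoundingBox(center, axes, hi - lo)


@dataclass(frozen=True)
class LegDimensions:
    """Average lower-leg OBB dimensions (descending), mm."""

    length: float
    width: float
    height: float

    @property
    def volume(self) -> float:
        return self.length * self.width * self.height


class FrameCategory(str, Enum):
    TWO_LEGS = "two_legs"
    SINGLE_LEG = "single_leg"
    MERGED_SINGLE_CLUSTER = "merged_single_cluster"
    INVALID = "invalid"


@dataclass
class FrameSegmentation:
    """Classification of one frame's clusters plus the leg clouds found."""

    category: FrameCategory
    legs: list[PointCloud] = field(default_factory=list)
    cluster_sizes: list[int] = field(default_factory=list)
    cluster_volumes: list[float] = field(default_factory=list)
    timestamp: float | None = None


def classify_frame(clusters: list[PointCloud], avg: LegDimensions | None,
                   min_points: int = MIN_CLUSTER_POINTS,
                   volume_bands: tuple[float, float, float] = (0.75, 1.25, 2.0)) -> FrameSegmentation:
    """Apply the cluster count/volume rules to one frame.

    Two clusters, each with at least ``min_points`` points and OBB volume
    above 0.75x the average leg volume, are two legs; one such cluster with
    volume in [0.75, 1.25]x average is a single leg; one cluster above 2x
    average is two legs merged.  Anything else is ignored.  With ``avg``
    None (bootstrap, before an average exists) only the two-cluster point
    count rule is applied.
    """
    lo, hi, merged = volume_bands
    ts = clusters[0].timestamp if clusters else None
    big = [c for c in clusters if len(c) >= min_points]
    sizes = [len(c) for c in big]
    vols: list[float] = []
    for c in big:
        try:
            vols.append(oriented_bounding_box(c).volume)
        except ValueError:
            vols.append(0.0)
    seg = FrameSegmentation(FrameCategory.INVALID, [], sizes, vols, ts)
    if avg is None:
        if len(big) == 2:
            seg.category = FrameCategory.TWO_LEGS
            seg.legs = big[:2]
        return seg
    av = avg.volume
    if len(big) >= 2 and all(v > lo * av for v in vols[:2]):
        seg.category = FrameCategory.TWO_LEGS
        seg.legs = big[:2]
    elif len(big) == 1 and lo * av <= vols[0] <= hi * av:
        seg.category = FrameCategory.SINGLE_LEG
        seg.legs = big[:1]
    elif len(big) == 1 and vols[0] > merged * av:
        seg.category = FrameCategory.MERGED_SINGLE_CLUSTER
        seg.legs = big[:1]
    return seg


def _trimmed_center_mean(values: np.ndarray, keep: int) -> float:
    srt = np.sort(np.asarray(values, dtype=float))
    n = len(srt)
    lo = (n - keep) // 2
    return float(srt[lo:lo + keep].mean())


def average_leg_dimensions(frames, n_obs: int = 40, keep: int = 20) -> LegDimensions:
    """Centre-trimmed mean of per-leg OBB dimensions over calibration frames.

    Collects one (l, w, h) observation (descending OBB extents) per leg from
    two-leg frames until ``n_obs`` observations exist; each dimension is
    sorted independently and the central ``keep`` values averaged.
    """
    obs = []
    for seg in frames:
        if seg.category is not FrameCategory.TWO_LEGS:
            continue
        for leg in seg.legs:
            try:
                obb = oriented_bounding_box(leg)
            except ValueError:
                continue
            obs.append(np.sort(obb.dims)[::-1])
            if len(obs) == n_obs:
                break
        if len(obs) == n_obs:
            break
    if len(obs) < n_obs:
        raise ValueError(f"insufficient data: {len(obs)}/{n_obs} valid leg observations")
    arr = np.array(obs)
    return LegDimensions(*(_trimmed_center_mean(arr[:, i], keep) for i in range(3)))


def moving_points_segmentation(pc_t: PointCloud, pc_ref: PointCloud,
                               match_radius: float = MATCH_RADIUS_MM,
                               min_fraction: float = MOVING_SPLIT_MIN_FRACTION,
                               outlier_k: int = 100) -> tuple[PointCloud, PointCloud]:
    """Split a merged two-leg cloud into non-moving and moving legs.

    Points of ``pc_t`` within ``match_radius`` mm of any reference point are
    the non-moving (stance) leg; the rest are the swinging leg.  Each side
    must hold at least ``min_fraction`` of the points or the frame is
    rejected.  Both sides are then cleaned with the statistical outlier
    filter and reduced to their biggest Euclidean cluster.
    """
    if len(pc_t) == 0 or len(pc_ref) == 0:
        raise ValueError("empty cloud in moving-points segmentation")
    tree = cKDTree(pc_ref.points)
    dist, _ = tree.query(pc_t.points, k=1, distance_upper_bound=match_radius)
    static_mask = np.isfinite(dist)
    n = len(pc_t)
    n_static = int(static_mask.sum())
    if n_static < min_fraction * n or (n - n_static) < min_fraction * n:
        raise ValueError(
            f"moving-points split failed the {min_fraction:.0%} rule "
            f"({n_static}/{n} static)"
        )
    halves = []
    for mask in (static_mask, ~static_mask):
        half = pc_t.with_points(pc_t.points[mask])
        half = statistical_outlier_filter(half, k=outlier_k)
        clusters = euclidean_cluster(half)
        halves.append(clusters[0] if clusters else half)
    return halves[0], halves[1]


def find_reference_frame(history, now: float | None = None,
                         max_age: float = REFERENCE_MAX_AGE_S) -> PointCloud:
    """Choose the stance-leg reference cloud from recent frames.

    The reference is the most recent frame (within ``max_age`` seconds of
    ``now`` when given) categorised two-legs or single-leg.  For a two-leg
    frame the reference leg is the cluster whose centroid moved least since
    its previous observation — the stance leg, which is stationary by
    definition; without an earlier observation the bigger cluster is used.
    """
    history = list(history)
    usable = (FrameCategory.TWO_LEGS, FrameCategory.SINGLE_LEG)
    for i in range(len(history) - 1, -1, -1):
        seg = history[i]
        if seg.category not in usable:
            continue
        if now is not None and seg.timestamp is not None and now - seg.timestamp > max_age:
            break
        if seg.category is FrameCategory.SINGLE_LEG:
            return seg.legs[0]
        prev = next(
            (h for h in reversed(history[:i]) if h.category in usable and h.legs),
            None,
        )
        if prev is None:
            return seg.legs[0]
        prev_centroids = np.array([leg.points.mean(axis=0) for leg in prev.legs])
        moves = []
        for leg in seg.legs:
            c = leg.points.mean(axis=0)
            moves.append(np.linalg.norm(prev_centroids - c, axis=1).min())
        return seg.legs[int(np.argmin(moves))]
    raise ValueError("no usable reference frame in history")
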