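"""Foot tracking: average foot dimensions, bottom plane, fixed-size OBB fit.

The foot is found inside a leg cloud by volumetric slicing: the cloud is cut
into 12 equal-height horizontal slices, per-slice OBB volumes are median
filtered (size 3), and scanning upward from the maximum-volume slice, the
first slice below 60% of the maximum marks the top of the foot.  Foot OBB
dimensions are averaged over 40 observations (centre-20 trimmed mean) and
then held fixed: every frame a box with exactly those dimensions is fitted —
base on the foot's bottom plane, in-plane yaw from 2-D PCA of the foot's
mid-band points — which counteracts cloud elongation from floor-contact
noise.  Heel and toe are the midpoints of the back/front bottom box edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pointcloud import PointCloud
from .segmentation import oriented_bounding_box

__all__ = [
    "FootDimensions",
    "FloorPlane",
    "FootBox",
    "FootLandmarks",
    "slice_volumes",
    "median3",
    "foot_cutoff_slice",
    "extract_foot_points",
    "foot_dimensions",
    "foot_bottom_plane",
    "fit_foot_box",
    "translate_workspace",
    "assign_left_right",
    "heel_toe_points",
]

WORKSPACE_SHIFT_MM = 5000.0
N_SLICES = 12
SLICE_CUTOFF_FRACTION = 0.6
PLANE_BAND_MM = 25.0
PLANE_INLIER_MM = 5.0
PLANE_MAX_TILT_DEG = 30.0
MIN_CENTER_POINTS = 50
MIN_AP_DISPLACEMENT_MM = 200.0


@dataclass(frozen=True)
class FootDimensions:
    """Average foot extents, mm: length > width, plus height."""

    length: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if not (self.length > self.width > 0 and self.height > 0):
            raise ValueError("foot dimensions must satisfy length > width > 0, height > 0")


@dataclass(frozen=True)
class FloorPlane:
    """A plane as unit normal (oriented upward) and offset: n.p = d."""

    normal: np.ndarray
    offset: float

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return np.atleast_2d(points) @ self.normal - self.offset

    def project(self, points: np.ndarray) -> np.ndarray:
        d = self.signed_distance(points)
        return np.atleast_2d(points) - d[:, None] * self.normal


@dataclass(frozen=True)
class FootBox:
    """A fixed-dimension oriented box around the foot at one frame.

    ``rotation`` columns are (length axis, width axis, height axis); the
    dims always equal the average foot dimensions; the base face lies on
    the fitted bottom plane.
    """

    position: np.ndarray          # centroid of the foot cloud (the tracked POS)
    center: np.ndarray            # geometric box centre (base snapped to the plane)
    rotation: np.ndarray
    dims: np.ndarray              # (f_l, f_w, f_h)
    plane: FloorPlane
    timestamp: float | None = None


@dataclass(frozen=True)
class FootLandmarks:
    heel: np.ndarray
    toe: np.ndarray
    side: str                     # "left" / "right" / "unassigned"
    timestamp: float | None = None


def median3(values: np.ndarray) -> np.ndarray:
    """Size-3, stride-1 median filter with the end points untouched."""
    v = np.asarray(values, dtype=float)
    out = v.copy()
    if len(v) >= 3:
        stacked = np.stack([v[:-2], v[1:-1], v[2:]])
        out[1:-1] = np.median(stacked, axis=0)
    return out


def slice_volumes(leg: PointCloud, n_slices: int = N_SLICES) -> tuple[np.ndarray, np.ndarray]:
    """OBB volume of the points in each of ``n_slices`` equal-height slices.

    Returns (volumes, slice_edges) where edges has n_slices + 1 z values
    spanning the cloud's vertical extent.  Slices with fewer than 4 points
    (no meaningful box) get volume 0.
    """
    z = leg.points[:, 2]
    if len(z) == 0:
        raise ValueError("empty leg cloud")
    edges = np.linspace(z.min(), z.max(), n_slices + 1)
    idx = np.clip(np.searchsorted(edges, z, side="right") - 1, 0, n_slices - 1)
    vols = np.zeros(n_slices)
    for s in range(n_slices):
        pts = leg.points[idx == s]
        if len(pts) < 4:
            continue
        try:
            vols[s] = oriented_bounding_box(pts).volume
        except ValueError:
            vols[s] = 0.0
    return vols, edges


def foot_cutoff_slice(volumes: np.ndarray, cutoff: float = SLICE_CUTOFF_FRACTION) -> int:
    """Index of the slice marking the top of the foot.

    After median filtering, find the maximum-volume slice and scan upward to
    the first slice whose volume drops below ``cutoff`` times the maximum.
    Points below that slice belong to the foot.
    """
    filt = median3(volumes)
    m = int(np.argmax(filt))
    vmax = filt[m]
    if vmax <= 0:
        raise ValueError("all slice volumes are zero (malformed cloud)")
    for s in range(m + 1, len(filt)):
        if filt[s] < cutoff * vmax:
            return s
    return len(filt)


def extract_foot_points(leg: PointCloud, n_slices: int = N_SLICES,
                        cutoff: float = SLICE_CUTOFF_FRACTION) -> PointCloud:
    """The points below the cut-off slice — the foot part of a leg cloud."""
    vols, edges = slice_volumes(leg, n_slices)
    s = foot_cutoff_slice(vols, cutoff)
    return leg.with_points(leg.points[leg.points[:, 2] < edges[s]])


def _foot_dims_one_frame(leg: PointCloud) -> np.ndarray:
    """(f_l, f_w, f_h) for one leg cloud, axis-aware.

    Height is the OBB extent along the most vertical axis; of the two
    remaining extents the larger is the length and the smaller the width.
    """
    foot = extract_foot_points(leg)
    if len(foot) < 10:
        raise ValueError("too few foot points below the cut-off slice")
    obb = oriented_bounding_box(foot)
    vert = int(np.argmax(np.abs(obb.rotation[2, :])))
    f_h = obb.dims[vert]
    rest = sorted((obb.dims[i] for i in range(3) if i != vert), reverse=True)
    return np.array([rest[0], rest[1], f_h])


def foot_dimensions(valid_leg_frames, n_obs: int = 40, keep: int = 20) -> FootDimensions:
    """Average foot dimensions over ``n_obs`` leg clouds (centre-20 trim)."""
    obs = []
    for leg in valid_leg_frames:
        try:
            obs.append(_foot_dims_one_frame(leg))
        except ValueError:
            continue
        if len(obs) == n_obs:
            break
    if len(obs) < n_obs:
        raise ValueError(f"insufficient data: {len(obs)}/{n_obs} foot observations")
    arr = np.array(obs)

    def trim(col):
        srt = np.sort(col)
        lo = (len(srt) - keep) // 2
        return float(srt[lo:lo + keep].mean())

    return FootDimensions(trim(arr[:, 0]), trim(arr[:, 1]), trim(arr[:, 2]))


def foot_bottom_plane(leg: PointCloud, rng: np.random.Generator | None = None,
                      band: float = PLANE_BAND_MM, inlier: float = PLANE_INLIER_MM,
                      iterations: int = 300,
                      max_tilt_deg: float = PLANE_MAX_TILT_DEG,
                      min_support_extent: float = 120.0) -> FloorPlane:
    """Robust consensus fit of the plantar-surface plane.

    Candidate planes are sampled from point triplets in the lowest ``band``
    mm of the leg cloud; candidates tilted more than ``max_tilt_deg`` from
    vertical are rejected.  Candidates are scored by inlier count (at
    ``inlier`` mm) minus a penalty for points lying below the plane — the
    plantar plane supports the foot, so a correct candidate leaves almost
    nothing underneath — and near-tied candidates are broken toward the
    lowest plane, which keeps the fit on the plantar surface rather than
    partway up the side walls.  The winner is refit by least squares on its
    inliers.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    pts = leg.points
    z = pts[:, 2]
    band_pts = pts[z < z.min() + band]
    if len(band_pts) < 10:
        raise ValueError("too few low points to fit a bottom plane")
    cos_max = np.cos(np.deg2rad(max_tilt_deg))
    n_band = len(band_pts)
    # all candidate triplets at once
    idx = np.array([rng.choice(n_band, 3, replace=False) for _ in range(iterations)])
    tri = band_pts[idx]                                   # (I, 3, 3)
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norms = np.linalg.norm(normals, axis=1)
    ok = norms > 1e-9
    normals[ok] /= norms[ok, None]
    normals[normals[:, 2] < 0] *= -1
    ok &= normals[:, 2] >= cos_max
    if not ok.any():
        raise ValueError("no plane candidate within the tilt limit (no plantar surface?)")
    normals = normals[ok]
    offsets = np.einsum("ij,ij->i", tri[ok, 0], normals)
    dist = band_pts @ normals.T - offsets                 # (B, I_ok)
    inl = np.abs(dist) <= inlier
    below = (dist < -inlier).sum(axis=0)
    counts = inl.sum(axis=0)
    scores = counts - 3 * below
    best_score = scores.max()
    if best_score <= 0:
        raise ValueError("no supporting plane consensus (no plantar surface?)")
    viable = np.flatnonzero(scores >= 0.95 * best_score)
    mean_h = np.where(counts[viable] > 0,
                      (band_pts[:, 2][:, None] * inl[:, viable]).sum(axis=0)
                      / np.maximum(counts[viable], 1), np.inf)
    # near-ties break first toward the least tilted plane (in 5-degree
    # bins), then toward the lowest one: with a partially visible wall
    # ring, tilted planes through a bottom edge can reach the same support
    # as the true plantar plane, but the true plane is the flattest of them
    tilt_bin = np.floor(np.degrees(np.arccos(np.clip(normals[viable, 2], -1, 1))) / 5.0)
    order = np.lexsort((mean_h, tilt_bin))
    pick = viable[order[0]]
    n = normals[pick]
    inl = inl[:, pick]
    # least-squares refit of the normal on the consensus inliers; the offset
    # is anchored at the low edge of the inlier slab because the plantar
    # plane SUPPORTS the foot — it touches the lowest consensus points
    # rather than averaging through the slab
    sel = band_pts[inl]
    ctr = sel.mean(axis=0)
    # plausibility: plantar support must be foot-sized — a shank cylinder's
    # bottom ring (or any sub-foot structure) cannot carry a bottom plane
    extent = (sel - ctr).max(axis=0) - (sel - ctr).min(axis=0)
    if np.linalg.norm(extent[:2]) < 1e-12 or extent.max() < min_support_extent:
        raise ValueError("plane support smaller than a foot (no plantar surface?)")
    u, s, vt = np.linalg.svd(sel - ctr, full_matrices=False)
    normal = vt[2]
    if normal[2] < 0:
        normal = -normal
    if normal[2] < cos_max:
        normal = n  # keep the consensus normal if the refit tilted away
    offset = float(np.percentile(sel @ normal, 10.0))
    return FloorPlane(normal, offset)


def fit_foot_box(leg: PointCloud, plane: FloorPlane, fd: FootDimensions,
                 min_center_points: int = MIN_CENTER_POINTS) -> FootBox:
    """Fit the fixed-dimension foot box for one frame.

    Points within ``f_h`` above the plane are the foot cloud; the slab
    between 0.1 and 0.9 f_h is projected onto the plane and 2-D PCA of the
    projection gives the in-plane yaw (the OBB axis-estimation step on
    projected points).  The extents map smallest -> f_h (the plane normal by
    construction), largest -> f_l, remaining -> f_w; the box base is snapped
    onto the plane and the tracked position is the foot-cloud centroid.
    """
    d = plane.signed_distance(leg.points)
    foot_mask = (d >= -PLANE_INLIER_MM) & (d <= fd.height)
    pc_foot = leg.points[foot_mask]
    center_mask = (d >= 0.1 * fd.height) & (d <= 0.9 * fd.height)
    pc_center = leg.points[center_mask]
    if len(pc_center) < min_center_points:
        raise ValueError(
            f"tracking lost: {len(pc_center)} centre-band points < {min_center_points}"
        )
    # the base of the box must touch the sole: if the bulk of the foot
    # cloud floats well above the plane, the plane locked onto something
    # else (e.g. remnants of the other foot near the floor) — skip the frame
    if len(pc_foot):
        if np.percentile(d[foot_mask], 10.0) > 0.25 * fd.height:
            raise ValueError("tracking lost: fitted plane does not support the foot")
    proj = plane.project(pc_center)
    ctr = proj.mean(axis=0)
    dd = proj - ctr
    cov = dd.T @ dd / len(proj)
    evals, evecs = np.linalg.eigh(cov)
    # in-plane axes: largest two eigenvalues; third axis is the plane normal
    e1 = evecs[:, 2]
    e2 = evecs[:, 1]
    e1 = e1 - (e1 @ plane.normal) * plane.normal
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(plane.normal, e1)
    rotation = np.stack([e1, e2, plane.normal], axis=1)
    dims = np.array([fd.length, fd.width, fd.height])
    pos = pc_foot.mean(axis=0) if len(pc_foot) else pc_center.mean(axis=0)
    # base face on the plane: keep the in-plane components of the centroid,
    # lift the centre half a height along the normal
    in_plane = plane.project(pos[None, :])[0]
    center = in_plane + (fd.height / 2) * plane.normal
    return FootBox(pos, center, rotation, dims, plane, leg.timestamp)


def translate_workspace(pc: PointCloud, shift: float = WORKSPACE_SHIFT_MM) -> PointCloud:
    """Shift x and y by +``shift`` mm so the walkway sits in the positive
    quadrant; landmarks are reported back in the un-translated frame."""
    return pc.translated(np.array([shift, shift, 0.0]))


def walking_direction(centroids: np.ndarray, min_displacement: float = MIN_AP_DISPLACEMENT_MM) -> int:
    """+1 for walking towards +y, -1 towards -y, from a centroid trajectory."""
    c = np.asarray(centroids, dtype=float)
    disp = c[-1, 1] - c[0, 1]
    if abs(disp) < min_displacement:
        raise ValueError("walking direction indeterminate (AP displacement too small)")
    return 1 if disp > 0 else -1


def assign_left_right(track_a: np.ndarray, track_b: np.ndarray,
                      min_displacement: float = MIN_AP_DISPLACEMENT_MM) -> tuple[str, str, int]:
    """Label two foot-box centroid tracks as left/right.

    The walking direction is the sign of the overall AP displacement of the
    centroid paths.  Walking towards the origin (decreasing y) the foot
    closer to the y-axis (smaller median |x|) is the right foot; walking
    away, the opposite.  Returns (side_of_a, side_of_b, direction).
    """
    a = np.asarray(track_a, dtype=float)
    b = np.asarray(track_b, dtype=float)
    disp = (a[-1, 1] - a[0, 1]) + (b[-1, 1] - b[0, 1])
    if abs(disp) < min_displacement:
        raise ValueError("walking direction indeterminate (AP displacement too small)")
    direction = 1 if disp > 0 else -1
    # median |x|: robust to transient ML excursions at coverage edges
    xa = np.median(np.abs(a[:, 0]))
    xb = np.median(np.abs(b[:, 0]))
    a_closer = xa < xb
    if direction < 0:   # towards the origin
        side_a = "right" if a_closer else "left"
    else:
        side_a = "left" if a_closer else "right"
    side_b = "left" if side_a == "right" else "right"
    return side_a, side_b, direction


def heel_toe_points(box: FootBox, direction: int) -> tuple[np.ndarray, np.ndarray]:
    """Heel and toe landmarks from the box corners.

    The bottom face is the 4 corners nearest the bottom plane; the toe is
    the midpoint of the 2 bottom corners furthest along the walking
    direction and the heel the midpoint of the rearmost 2.  By construction
    ``|toe - heel| = f_l``.
    """
    f_l, f_w, f_h = box.dims
    e1, e2, n = box.rotation[:, 0], box.rotation[:, 1], box.rotation[:, 2]
    base = box.center - (f_h / 2) * n
    ends = [base + (f_l / 2) * e1, base - (f_l / 2) * e1]
    # order the two bottom-edge midpoints along the walking direction (AP = y)
    ends.sort(key=lambda p: direction * p[1])
    heel, toe = ends[0], ends[1]
    return heel, toe
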