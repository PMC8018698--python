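"""Lower-leg cropping, clustering, OBB fitting and leg classification."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from stridehall.pointcloud import PointCloud
from stridehall.segmentation import (FrameCategory, FrameSegmentation,
                                     LegDimensions, average_leg_dimensions,
                                     classify_frame, crop_lower,
                                     euclidean_cluster, find_reference_frame,
                                     moving_points_segmentation,
                                     oriented_bounding_box)


def cluster_oracle(points, tol):
    """Union-find over the <= tol adjacency graph (independent oracle)."""
    n = len(points)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(points[i] - points[j]) <= tol:
                parent[find(i)] = find(j)
    labels = np.array([find(i) for i in range(n)])
    return labels


def partitions_equal(clusters, points, labels):
    got = {frozenset(map(tuple, c.points)) for c in clusters}
    want = {frozenset(map(tuple, points[labels == lab])) for lab in set(labels)}
    return got == want


class TestCropLower:
    def test_threshold(self):
        pc = PointCloud([[0, 0, 699.0], [0, 0, 701.0], [0, 0, 700.0]])
        out = crop_lower(pc)
        assert list(out.points[:, 2]) == [699.0]

    def test_empty(self):
        assert len(crop_lower(PointCloud(np.empty((0, 3))))) == 0


class TestEuclideanCluster:
    def test_two_separated_blobs(self, rng):
        a = rng.normal(0, 10, (500, 3))
        b = rng.normal(0, 10, (500, 3)) + [200, 0, 0]
        clusters = euclidean_cluster(PointCloud(np.vstack([a, b])))
        assert len(clusters) == 2

    def test_chain_within_tolerance_is_one_cluster(self):
        pts = np.column_stack([np.arange(0, 490, 49.0), np.zeros(10), np.zeros(10)])
        assert len(euclidean_cluster(PointCloud(pts))) == 1

    def test_matches_union_find_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 120))
            pts = rng.uniform(0, 300, (n, 3))
            clusters = euclidean_cluster(PointCloud(pts), tolerance=50.0)
            labels = cluster_oracle(pts, 50.0)
            assert partitions_equal(clusters, pts, labels)

    def test_sorted_by_size_descending(self, rng):
        a = rng.normal(0, 5, (300, 3))
        b = rng.normal(0, 5, (100, 3)) + [500, 0, 0]
        clusters = euclidean_cluster(PointCloud(np.vstack([b, a])))
        assert len(clusters[0]) >= len(clusters[1])


def box_points(dims, n=800, rng=None):
    rng = rng or np.random.default_rng(7)
    return rng.uniform(-0.5, 0.5, (n, 3)) * np.asarray(dims)


def grid_box(dims, step=8.0):
    """Points filling a box on a regular grid (exact extents and symmetry)."""
    axes = [np.linspace(-d / 2, d / 2, max(2, int(d / step) + 1)) for d in dims]
    g = np.meshgrid(*axes, indexing="ij")
    return np.stack([a.ravel() for a in g], axis=1)


class TestOrientedBoundingBox:
    def test_axis_aligned_box_dims(self, rng):
        pts = box_points([100, 40, 20], 2000, rng)
        obb = oriented_bounding_box(PointCloud(pts))
        np.testing.assert_allclose(np.sort(obb.dims)[::-1], [100, 40, 20], rtol=0.03)
        # rotation close to a signed permutation
        assert np.allclose(np.abs(obb.rotation) @ np.abs(obb.rotation.T), np.eye(3), atol=0.05)

    def test_rotated_box_recovers_dims(self):
        pts = grid_box([100, 40, 20], step=4.0)
        r = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        obb = oriented_bounding_box(PointCloud(pts @ r.T))
        np.testing.assert_allclose(np.sort(obb.dims)[::-1], [100, 40, 20], rtol=0.02)

    def test_volume_never_exceeds_aabb_volume(self, rng):
        pts = box_points([80, 50, 30], 2000, rng)
        for _ in range(20):
            r = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
            q = pts @ r.T
            obb = oriented_bounding_box(PointCloud(q))
            aabb = np.prod(q.max(axis=0) - q.min(axis=0))
            assert obb.volume <= aabb * (1 + 1e-9)

    def test_contains_all_points(self, rng):
        pts = rng.normal(0, 30, (500, 3)) * [3, 1, 0.5]
        obb = oriented_bounding_box(PointCloud(pts))
        assert obb.contains(pts).all()

    def test_degenerate_rejected(self):
        line = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        with pytest.raises(ValueError):
            oriented_bounding_box(PointCloud(line))
        with pytest.raises(ValueError):
            oriented_bounding_box(PointCloud(np.zeros((2, 3))))


def seg_two(n=1500, vol_scale=1.0, rng=None):
    rng = rng or np.random.default_rng(0)
    dims = np.array([400.0, 150.0, 100.0]) * vol_scale ** (1 / 3)
    legs = [PointCloud(box_points(dims, n, rng) + [off, 0, 0]) for off in (0, 1000)]
    return legs


class TestClassifyFrame:
    def avg(self):
        return LegDimensions(400.0, 150.0, 100.0)

    def test_two_legs(self, rng):
        legs = seg_two(1500, 0.9, rng)
        seg = classify_frame(legs, self.avg())
        assert seg.category is FrameCategory.TWO_LEGS
        assert len(seg.legs) == 2

    def test_merged_single_cluster(self, rng):
        big = PointCloud(box_points([700, 300, 130], 3000, rng))  # > 2x avg volume
        seg = classify_frame([big], self.avg())
        assert seg.category is FrameCategory.MERGED_SINGLE_CLUSTER

    def test_between_bands_is_invalid(self, rng):
        mid = PointCloud(box_points([470, 180, 115], 3000, rng))  # ~1.6x avg volume
        seg = classify_frame([mid], self.avg())
        assert seg.category is FrameCategory.INVALID

    def test_single_leg(self, rng):
        one = PointCloud(box_points([400, 150, 100], 2000, rng))
        seg = classify_frame([one], self.avg())
        assert seg.category is FrameCategory.SINGLE_LEG

    def test_small_clusters_ignored(self, rng):
        legs = [PointCloud(box_points([400, 150, 100], 200, rng))]
        seg = classify_frame(legs, self.avg())
        assert seg.category is FrameCategory.INVALID

    def test_bootstrap_mode_counts_only(self, rng):
        legs = seg_two(1500, 1.0, rng)
        seg = classify_frame(legs, None)
        assert seg.category is FrameCategory.TWO_LEGS


class TestAverageLegDimensions:
    def make_frames(self, dims_list, rng):
        frames = []
        for dims in dims_list:
            legs = [PointCloud(box_points(dims, 1500, rng)),
                    PointCloud(box_points(dims, 1500, rng) + [1000, 0, 0])]
            frames.append(FrameSegmentation(FrameCategory.TWO_LEGS, legs))
        return frames

    def test_identical_observations(self, rng):
        frames = self.make_frames([[400, 150, 100]] * 20, rng)
        avg = average_leg_dimensions(frames)
        assert avg.length == pytest.approx(400, rel=0.03)
        assert avg.width == pytest.approx(150, rel=0.03)
        assert avg.height == pytest.approx(100, rel=0.05)

    def test_trimmed_mean_excludes_planted_outliers(self):
        # synthetic dimension observations fed straight to the trimming rule
        from stridehall.segmentation import _trimmed_center_mean

        vals = np.concatenate([np.full(10, -1e3), np.full(20, 50.0), np.full(10, 1e3)])
        assert _trimmed_center_mean(vals, 20) == pytest.approx(50.0)

    def test_insufficient_frames(self, rng):
        frames = self.make_frames([[400, 150, 100]] * 5, rng)
        with pytest.raises(ValueError):
            average_leg_dimensions(frames)


class TestMovingPointsSegmentation:
    def test_identical_clouds_fail_30pct(self, rng):
        pts = rng.normal(0, 50, (400, 3))
        with pytest.raises(ValueError):
            moving_points_segmentation(PointCloud(pts), PointCloud(pts), outlier_k=20)

    def test_fully_shifted_cloud_fails_symmetrically(self, rng):
        pts = rng.normal(0, 50, (400, 3))
        with pytest.raises(ValueError):
            moving_points_segmentation(PointCloud(pts + 100), PointCloud(pts), outlier_k=20)

    def test_half_split_matches_nn_oracle(self, rng):
        ref = rng.uniform(0, 200, (300, 3))
        static_part = ref[:150]
        moving_part = ref[150:] + [500, 0, 0]
        pc_t = PointCloud(np.vstack([static_part, moving_part]))
        stat, mov = moving_points_segmentation(pc_t, PointCloud(ref), outlier_k=20)
        # oracle: any-reference-neighbour test at 20 mm
        d = np.linalg.norm(pc_t.points[:, None] - ref[None, :], axis=2).min(axis=1)
        want_static = pc_t.points[d <= 20.0]
        # the outlier filter and biggest-cluster step may shrink but not
        # mislabel: every returned static point is a true static point
        stat_set = {tuple(p) for p in want_static}
        assert all(tuple(p) in stat_set for p in stat.points)
        mov_set = {tuple(p) for p in pc_t.points[d > 20.0]}
        assert all(tuple(p) in mov_set for p in mov.points)


class TestFindReferenceFrame:
    def test_most_recent_two_leg_frame_stance_side(self, rng):
        stance = PointCloud(rng.normal(0, 30, (200, 3)), timestamp=0.0)
        swing0 = PointCloud(rng.normal(0, 30, (200, 3)) + [0, 300, 0], timestamp=0.0)
        swing1 = swing0.translated([0, 80, 0])  # moved since last frame
        h0 = FrameSegmentation(FrameCategory.TWO_LEGS, [stance, swing0], timestamp=0.0)
        h1 = FrameSegmentation(FrameCategory.TWO_LEGS,
                               [stance.translated([0, 0.5, 0]), swing1], timestamp=0.017)
        ref = find_reference_frame([h0, h1], now=0.033)
        assert np.allclose(ref.points.mean(axis=0), stance.points.mean(axis=0), atol=2)

    def test_all_invalid_history_raises(self):
        hist = [FrameSegmentation(FrameCategory.INVALID, [], timestamp=0.0)]
        with pytest.raises(ValueError):
            find_reference_frame(hist, now=0.017)

    def test_stale_history_raises(self, rng):
        old = FrameSegmentation(
            FrameCategory.SINGLE_LEG, [PointCloud(rng.normal(0, 30, (100, 3)))], timestamp=0.0)
        with pytest.raises(ValueError):
            find_reference_frame([old], now=1.0)
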