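"""Foot dimensions, bottom plane, fixed-box fitting and landmarks."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from stridehall.foot import (FootDimensions, assign_left_right, fit_foot_box,
                             foot_bottom_plane, foot_cutoff_slice,
                             foot_dimensions, heel_toe_points, median3,
                             translate_workspace)
from stridehall.pointcloud import PointCloud


def grid_surface_foot(f_l=250.0, f_w=90.0, f_h=80.0, step=4.0, bottom=True,
                      shank=True, shank_r=40.0, shank_len=500.0):
    """A synthetic leg cloud: surface-sampled foot box plus a thin shank."""
    pts = []
    xs = np.arange(-f_w / 2, f_w / 2 + 1e-9, step)
    ys = np.arange(0, f_l + 1e-9, step)
    zs = np.arange(0, f_h + 1e-9, step)
    for z in zs:   # side walls
        for y in ys:
            pts += [[-f_w / 2, y, z], [f_w / 2, y, z]]
        for x in xs:
            pts += [[x, 0.0, z], [x, f_l, z]]
    for y in ys:   # top (and optionally bottom) faces
        for x in xs:
            pts.append([x, y, f_h])
            if bottom:
                pts.append([x, y, 0.0])
    if shank:
        a = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        for z in np.arange(f_h, f_h + shank_len, step):
            for t in a:
                pts.append([shank_r * np.cos(t), f_l * 0.3 + shank_r * np.sin(t), z])
    return np.asarray(pts)


class TestFootDimensionHelpers:
    def test_median_filter_middle_replaced(self):
        np.testing.assert_allclose(median3([10, 100, 12]), [10, 12, 12])

    def test_median_filter_endpoints_untouched(self):
        v = median3([100, 1, 2, 3, 100])
        assert v[0] == 100 and v[-1] == 100

    def test_cutoff_slice_rule(self):
        vols = [8, 10, 50, 60, 55, 20, 18, 17, 16, 15, 14, 13]
        # max 60, first slice scanning upward below 0.6*60=36 is index 5
        assert foot_cutoff_slice(np.array(vols, dtype=float)) == 5

    def test_cutoff_slice_no_drop_returns_end(self):
        vols = np.full(12, 50.0)
        assert foot_cutoff_slice(vols) == 12

    def test_cutoff_all_zero_rejected(self):
        with pytest.raises(ValueError):
            foot_cutoff_slice(np.zeros(12))


class TestFootDimensions:
    def test_recovers_synthetic_foot(self):
        leg = PointCloud(grid_surface_foot())
        fd = foot_dimensions([leg] * 40)
        assert fd.length == pytest.approx(250, abs=10)
        assert fd.width == pytest.approx(90, abs=10)

    def test_insufficient_frames(self):
        leg = PointCloud(grid_surface_foot())
        with pytest.raises(ValueError):
            foot_dimensions([leg] * 10)


class TestFootBottomPlane:
    def test_flat_resting_foot(self, rng):
        leg = PointCloud(grid_surface_foot())
        plane = foot_bottom_plane(leg, rng=rng)
        tilt = np.degrees(np.arccos(plane.normal[2]))
        assert tilt < 1.0
        assert abs(plane.offset / plane.normal[2]) < 2.0  # plane height ~ 0

    def test_pitched_foot_recovers_normal(self, rng):
        pts = grid_surface_foot(shank=False)
        r = Rotation.from_euler("x", 10, degrees=True).as_matrix()
        q = pts @ r.T
        q[:, 2] -= q[:, 2].min()
        plane = foot_bottom_plane(PointCloud(q), rng=rng)
        true_n = r @ np.array([0, 0, 1.0])
        angle = np.degrees(np.arccos(np.clip(plane.normal @ true_n, -1, 1)))
        assert angle < 2.0

    def test_pure_shank_rejected(self, rng):
        a = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        pts = []
        for z in np.arange(0, 400, 4.0):
            for t in a:
                pts.append([40 * np.cos(t), 40 * np.sin(t), z])
        with pytest.raises(ValueError):
            foot_bottom_plane(PointCloud(np.array(pts)), rng=rng)


FD = FootDimensions(250.0, 90.0, 80.0)


class TestFitFootBox:
    def test_resting_foot_center_and_axis(self, rng):
        pts = grid_surface_foot()
        leg = PointCloud(pts)
        plane = foot_bottom_plane(leg, rng=rng)
        box = fit_foot_box(leg, plane, FD)
        foot_only = pts[pts[:, 2] <= 80.0]
        np.testing.assert_allclose(box.position, foot_only.mean(axis=0), atol=15)
        # long axis along y
        assert abs(box.rotation[1, 0]) > np.cos(np.deg2rad(5))
        np.testing.assert_allclose(box.dims, [250, 90, 80])

    def test_dims_always_the_averages(self, rng):
        # a short instantaneous cloud still yields the fixed-size box
        pts = grid_surface_foot(f_l=180.0)
        leg = PointCloud(pts)
        plane = foot_bottom_plane(leg, rng=rng)
        box = fit_foot_box(leg, plane, FD)
        np.testing.assert_allclose(box.dims, [250, 90, 80])

    def test_floor_noise_patch_bounded_axis_deviation(self, rng):
        pts = grid_surface_foot()
        # an AP-elongated noise patch near the floor, as seen at foot strike
        patch = np.column_stack([rng.normal(0, 10, 300),
                                 rng.uniform(200, 420, 300),
                                 rng.uniform(0, 6, 300)])
        leg = PointCloud(np.vstack([pts, patch]))
        plane = foot_bottom_plane(leg, rng=rng)
        box = fit_foot_box(leg, plane, FD)
        axis = box.rotation[:, 0]
        dev = np.degrees(np.arccos(min(1.0, abs(axis[1]))))
        assert dev < 10.0

    def test_too_few_center_points(self, rng):
        leg = PointCloud(grid_surface_foot()[:40])
        from stridehall.foot import FloorPlane

        plane = FloorPlane(np.array([0, 0, 1.0]), 0.0)
        with pytest.raises(ValueError):
            fit_foot_box(leg, plane, FD)


class TestWorkspaceAndSides:
    def test_translate_and_inverse(self):
        pc = PointCloud([[0.0, 0, 0], [1, 2, 3]])
        out = translate_workspace(pc)
        np.testing.assert_allclose(out.points[0], [5000, 5000, 0])
        back = out.translated([-5000, -5000, 0])
        np.testing.assert_allclose(back.points, pc.points)

    def test_walking_towards_origin_right_is_closer_to_y_axis(self):
        t = np.linspace(0, 1, 50)
        a = np.column_stack([np.full(50, 5100.0), 5800 - 1000 * t, np.zeros(50)])
        b = np.column_stack([np.full(50, 5250.0), 5750 - 1000 * t, np.zeros(50)])
        sa, sb, direction = assign_left_right(a, b)
        assert direction == -1
        assert sa == "right" and sb == "left"

    def test_walking_away_labels_swap(self):
        t = np.linspace(0, 1, 50)
        a = np.column_stack([np.full(50, 5100.0), 4800 + 1000 * t, np.zeros(50)])
        b = np.column_stack([np.full(50, 5250.0), 4850 + 1000 * t, np.zeros(50)])
        sa, sb, direction = assign_left_right(a, b)
        assert direction == 1
        assert sa == "left" and sb == "right"

    def test_indeterminate_direction(self):
        a = np.tile([5100.0, 5000.0, 0.0], (30, 1))
        b = np.tile([5250.0, 5000.0, 0.0], (30, 1))
        with pytest.raises(ValueError):
            assign_left_right(a, b)


class TestHeelToe:
    def make_box(self, yaw_deg=0.0):
        from stridehall.foot import FloorPlane, FootBox

        r = Rotation.from_euler("z", yaw_deg, degrees=True).as_matrix()
        e1 = r @ np.array([0, 1.0, 0])
        e2 = r @ np.array([-1.0, 0, 0])
        rot = np.stack([e1, e2, [0, 0, 1.0]], axis=1)
        return FootBox(np.array([0, 0, 40.0]), np.array([0, 0, 40.0]), rot,
                       np.array([250.0, 90, 80]), FloorPlane(np.array([0, 0, 1.0]), 0.0))

    def test_walking_plus_y(self):
        heel, toe = heel_toe_points(self.make_box(), direction=1)
        assert toe[1] > heel[1]
        np.testing.assert_allclose(toe, [0, 125, 0], atol=1e-9)
        np.testing.assert_allclose(heel, [0, -125, 0], atol=1e-9)

    def test_walking_minus_y_swaps(self):
        heel, toe = heel_toe_points(self.make_box(), direction=-1)
        assert toe[1] < heel[1]

    def test_separation_is_foot_length(self):
        for yaw in (0, 15, -30, 80):
            heel, toe = heel_toe_points(self.make_box(yaw), direction=1)
            assert np.linalg.norm(toe - heel) == pytest.approx(250.0, abs=1e-9)

    def test_landmarks_on_bottom_plane(self):
        box = self.make_box(10)
        heel, toe = heel_toe_points(box, direction=1)
        assert abs(box.plane.signed_distance(heel[None])[0]) < 1e-9
        assert abs(box.plane.signed_distance(toe[None])[0]) < 1e-9
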