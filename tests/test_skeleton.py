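"""Chamfer transform vs shortest-path oracle; thinning topology; tracing;
smoothing; radius assignment."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from perfusemri import (
    ImageVolume,
    assign_radii,
    chamfer_distance_map,
    distance_ordered_thinning,
    mask_to_graph,
    smooth_line_set,
    trace_lines,
)
from perfusemri._kernels import CHAMFER_W, OFFSETS26
from perfusemri.graph import Segment, SpatialGraph

from conftest import straight_vessel_graph


def dijkstra_chamfer(mask: np.ndarray) -> np.ndarray:
    """Exact weighted shortest path from every background voxel (oracle)."""
    shape = mask.shape
    n = mask.size
    idx = np.arange(n).reshape(shape)
    rows, cols, weights = [], [], []
    for off, w in zip(OFFSETS26, CHAMFER_W):
        src = idx[
            max(0, off[0]) : shape[0] + min(0, off[0]),
            max(0, off[1]) : shape[1] + min(0, off[1]),
            max(0, off[2]) : shape[2] + min(0, off[2]),
        ]
        dst = idx[
            max(0, -off[0]) : shape[0] + min(0, -off[0]),
            max(0, -off[1]) : shape[1] + min(0, -off[1]),
            max(0, -off[2]) : shape[2] + min(0, -off[2]),
        ]
        rows.append(src.ravel())
        cols.append(dst.ravel())
        weights.append(np.full(src.size, w))
    g = coo_matrix(
        (np.concatenate(weights), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    bg = np.flatnonzero(~mask.ravel())
    d = dijkstra(g, indices=bg, min_only=True)
    return np.where(mask.ravel(), d, 0.0).reshape(shape)


def n_components_26(mask: np.ndarray) -> int:
    return ndimage.label(mask, structure=np.ones((3, 3, 3)))[1]


class TestChamferDistanceMap:
    def test_single_voxel_gets_face_weight(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        dm = chamfer_distance_map(ImageVolume(m, (1, 1, 1)))
        assert dm.values[2, 2, 2] == 3.0
        assert dm.values.sum() == 3.0

    def test_row_of_voxels_all_at_face_distance(self):
        # a 5x1x1 foreground row with background on all sides: every voxel is
        # one face step from side background
        m = np.zeros((7, 3, 3), bool)
        m[1:6, 1, 1] = True
        dm = chamfer_distance_map(ImageVolume(m, (1, 1, 1)))
        np.testing.assert_array_equal(dm.values[1:6, 1, 1], 3.0)
        np.testing.assert_allclose(dm.values, dijkstra_chamfer(m))

    def test_solid_cube_center_five_face_steps(self):
        m = np.zeros((11, 11, 11), bool)
        m[1:10, 1:10, 1:10] = True
        dm = chamfer_distance_map(ImageVolume(m, (1, 1, 1)))
        assert dm.values[5, 5, 5] == 15.0
        np.testing.assert_allclose(dm.values, dijkstra_chamfer(m))

    def test_equals_dijkstra_on_random_masks(self):
        rng = np.random.default_rng(21)
        for _ in range(15):
            shape = tuple(rng.integers(5, 21, 3))
            mask = rng.random(shape) < rng.uniform(0.2, 0.85)
            mask.flat[0] = False  # keep at least one background voxel
            dm = chamfer_distance_map(ImageVolume(mask, (1, 1, 1)))
            np.testing.assert_allclose(dm.values, dijkstra_chamfer(mask))

    def test_zero_on_background_positive_on_foreground(self):
        rng = np.random.default_rng(22)
        mask = rng.random((10, 10, 10)) < 0.5
        mask.flat[0] = False
        dm = chamfer_distance_map(ImageVolume(mask, (1, 1, 1)))
        assert np.all(dm.values[~mask] == 0)
        assert np.all(dm.values[mask] > 0)

    def test_empty_mask_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            dm = chamfer_distance_map(ImageVolume(np.zeros((4, 4, 4), bool), (1, 1, 1)))
        assert not dm.values.any()

    def test_mm_conversion_uses_face_weight(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        dm = chamfer_distance_map(ImageVolume(m, (0.5, 0.5, 0.5)))
        assert dm.to_mm()[2, 2, 2] == pytest.approx(0.5)


class TestDistanceOrderedThinning:
    def test_one_voxel_wide_straight_curve_unchanged(self):
        m = np.zeros((12, 5, 5), bool)
        m[2:10, 2, 2] = True
        skel = distance_ordered_thinning(chamfer_distance_map(ImageVolume(m, (1, 1, 1))))
        np.testing.assert_array_equal(skel.values, m)

    def test_one_voxel_wide_diagonal_curve_unchanged(self):
        m = np.zeros((12, 12, 5), bool)
        for i in range(2, 10):
            m[i, i, 2] = True
        skel = distance_ordered_thinning(chamfer_distance_map(ImageVolume(m, (1, 1, 1))))
        np.testing.assert_array_equal(skel.values, m)

    def test_cylinder_skeleton_lies_on_axis(self, cylinder_mask):
        mask, axis = cylinder_mask
        skel = distance_ordered_thinning(chamfer_distance_map(mask))
        coords = np.argwhere(skel.values)
        assert len(coords) > 0
        dist_to_axis = np.linalg.norm(coords[:, :2] - axis[0, :2], axis=1)
        assert np.mean(dist_to_axis <= 1.0) >= 0.95

    def test_solid_cube_single_component(self):
        m = np.zeros((9, 9, 9), bool)
        m[2:7, 2:7, 2:7] = True
        skel = distance_ordered_thinning(chamfer_distance_map(ImageVolume(m, (1, 1, 1))))
        assert skel.values.any()
        assert n_components_26(skel.values) == 1

    def test_topology_preserved_on_random_blobs(self):
        rng = np.random.default_rng(30)
        for _ in range(5):
            raw = rng.random((16, 16, 16))
            mask = ndimage.gaussian_filter(raw, 1.5) > 0.55
            if not mask.any():
                continue
            skel = distance_ordered_thinning(
                chamfer_distance_map(ImageVolume(mask, (1, 1, 1))), min_end_length=0
            )
            assert n_components_26(skel.values) == n_components_26(mask)
            assert np.all(mask[skel.values])  # skeleton subset of mask


class TestTraceLines:
    def test_straight_line_two_nodes_one_segment(self):
        m = np.zeros((10, 5, 5), bool)
        m[1:9, 2, 2] = True
        g = trace_lines(ImageVolume(m, (1, 1, 1)))
        assert g.n_nodes == 2
        assert g.n_segments == 1
        assert sorted(g.degrees().values()) == [1, 1]

    def test_y_shape_four_nodes_three_segments(self):
        m = np.zeros((16, 16, 5), bool)
        for i in range(2, 8):
            m[i, 8, 2] = True  # stem
        for i in range(8, 14):
            m[i, 8 + (i - 7), 2] = True  # upper arm (diagonal)
            m[i, 8 - (i - 7), 2] = True  # lower arm (diagonal)
        g = trace_lines(ImageVolume(m, (1, 1, 1)))
        degs = sorted(g.degrees().values())
        assert degs == [1, 1, 1, 3]
        assert g.n_segments == 3

    def test_closed_loop_one_node_coincident_ends(self):
        # diamond ring: every voxel has exactly two 26-neighbours
        m = np.zeros((11, 11, 3), bool)
        c, r = 5, 4
        for i in range(11):
            for j in range(11):
                if abs(i - c) + abs(j - c) == r:
                    m[i, j, 1] = True
        g = trace_lines(ImageVolume(m, (1, 1, 1)))
        assert g.n_nodes == 1
        assert g.n_segments == 1
        seg = g.segments[0]
        assert seg.node_a == seg.node_b
        np.testing.assert_allclose(seg.points[0], seg.points[-1])

    def test_thick_block_rejected(self):
        m = np.zeros((6, 6, 6), bool)
        m[1:4, 1:4, 1:4] = True
        with pytest.raises(ValueError, match="thinning"):
            trace_lines(ImageVolume(m, (1, 1, 1)))


class TestSmoothLineSet:
    def _graph(self, pts):
        pts = np.asarray(pts, dtype=float)
        seg = Segment(0, 1, pts, np.zeros(len(pts)))
        return SpatialGraph({0: pts[0], 1: pts[-1]}, [seg])

    def test_straight_polyline_is_fixed_point(self):
        pts = np.stack([np.linspace(0, 10, 11), np.zeros(11), np.zeros(11)], axis=1)
        out = smooth_line_set(self._graph(pts))
        np.testing.assert_allclose(out.segments[0].points, pts, atol=1e-12)

    def test_zigzag_curved_length_decreases(self):
        x = np.arange(11, dtype=float)
        y = np.where(x % 2 == 0, 0.0, 1.0)
        pts = np.stack([x, y, np.zeros(11)], axis=1)
        g = self._graph(pts)
        out = smooth_line_set(g)
        assert out.segments[0].curved_length_mm < g.segments[0].curved_length_mm

    def test_attach_one_smoothing_zero_is_identity(self):
        rng = np.random.default_rng(33)
        pts = rng.random((8, 3)) * 10
        g = self._graph(pts)
        out = smooth_line_set(g, iterations=10, smoothing=0.0, attach=1.0)
        np.testing.assert_allclose(out.segments[0].points, pts, atol=1e-12)

    def test_endpoints_anchored(self):
        rng = np.random.default_rng(34)
        pts = rng.random((9, 3)) * 5
        g = self._graph(pts)
        out = smooth_line_set(g)
        np.testing.assert_array_equal(out.segments[0].points[0], pts[0])
        np.testing.assert_array_equal(out.segments[0].points[-1], pts[-1])

    def test_coefficients_validated(self):
        with pytest.raises(ValueError):
            smooth_line_set(self._graph(np.zeros((3, 3))), smoothing=1.5)


class TestAssignRadii:
    def test_cylinder_axis_radius_within_half_voxel(self, cylinder_mask):
        mask, axis = cylinder_mask
        dm = chamfer_distance_map(mask)
        mid = axis[len(axis) // 2]
        pts = np.array([mask.voxel_to_world(mid.astype(float))])
        pts = np.vstack([pts, pts + [0.0, 0.0, 1.0]])
        seg = Segment(0, 1, pts, np.zeros(2))
        g = SpatialGraph({0: pts[0], 1: pts[1]}, [seg])
        out = assign_radii(g, dm)
        assert out.segments[0].radii_mm[0] == pytest.approx(3.0, abs=0.5)

    def test_point_on_background_gets_zero_and_warns(self, cylinder_mask):
        mask, _ = cylinder_mask
        dm = chamfer_distance_map(mask)
        pts = np.array([[0.5, 0.5, 0.5], [1.5, 0.5, 0.5]])  # outside the vessel
        g = SpatialGraph({0: pts[0], 1: pts[1]}, [Segment(0, 1, pts, np.zeros(2))])
        with pytest.warns(UserWarning, match="background|foreground"):
            out = assign_radii(g, dm)
        assert out.segments[0].radii_mm[0] == 0.0

    def test_radius_spacing_invariant_in_mm(self):
        # same physical 3 mm cylinder sampled at 1 mm and 0.5 mm voxels
        radii = {}
        for spacing in (1.0, 0.5):
            n = int(round(12 / spacing))
            nz = int(round(30 / spacing))
            m = np.zeros((n, n, nz), bool)
            c = (np.arange(n) + 0.5) * spacing
            x, y = np.meshgrid(c, c, indexing="ij")
            m[(x - 6) ** 2 + (y - 6) ** 2 <= 9.0, :] = True
            vol = ImageVolume(m, (spacing,) * 3)
            dm = chamfer_distance_map(vol)
            center = np.array([[6.0, 6.0, 15.0], [6.0, 6.0, 16.0]])
            g = SpatialGraph(
                {0: center[0], 1: center[1]}, [Segment(0, 1, center, np.zeros(2))]
            )
            radii[spacing] = assign_radii(g, dm).segments[0].radii_mm[0]
        assert abs(radii[1.0] - radii[0.5]) <= 0.5  # within half a coarse voxel


class TestFullChainOnCylinder:
    def test_mask_to_graph_recovers_single_segment(self, cylinder_mask):
        mask, axis = cylinder_mask
        g = mask_to_graph(mask)
        assert g.n_segments == 1
        assert sorted(g.degrees().values()) == [1, 1]
        seg = g.segments[0]
        assert np.median(seg.radii_mm[2:-2]) == pytest.approx(3.0, abs=0.5)
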