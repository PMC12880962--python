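"""Shared phantom builders for the test suite.

Everything is generated programmatically; no image data is stored.
"""

from __future__ import annotations

import numpy as np
import pytest

from perfusemri import ImageVolume, PhantomSpec, SpatialGraph
from perfusemri.graph import Segment


@pytest.fixture
def cylinder_mask():
    """Solid cylinder of radius 3 voxels along z (1 mm voxels), plus its axis."""
    shape = (13, 13, 60)
    m = np.zeros(shape, dtype=bool)
    x, y = np.meshgrid(np.arange(13), np.arange(13), indexing="ij")
    disk = (x - 6) ** 2 + (y - 6) ** 2 <= 9.0
    m[disk, :] = True
    m[:, :, 0] = False
    m[:, :, -1] = False
    axis = np.array([[6, 6, z] for z in range(1, 59)])
    return ImageVolume(m, (1.0, 1.0, 1.0)), axis


def straight_vessel_graph(
    length_mm: float = 120.0,
    radius_mm: float = 5.0,
    start=(8.0, 16.0, 16.0),
    n_points: int | None = None,
) -> SpatialGraph:
    """Single straight segment along +x with constant radius."""
    n = n_points or int(length_mm) + 1
    pts = np.stack(
        [
            np.linspace(start[0], start[0] + length_mm, n),
            np.full(n, start[1]),
            np.full(n, start[2]),
        ],
        axis=1,
    )
    seg = Segment(0, 1, pts, np.full(n, radius_mm))
    return SpatialGraph({0: pts[0], 1: pts[-1]}, [seg], inlet_node=0)


def binary_tree_graph(depth: int = 3, length: float = 20.0) -> SpatialGraph:
    """Planar binary tree with an inlet segment; exact analytic geometry."""
    nodes = {0: np.array([0.0, 0.0, 0.0])}
    segments = []
    frontier = [(0, np.array([0.0, 0.0, 0.0]), np.array([1.0, 0.0, 0.0]))]
    next_id = 1
    for gen in range(1, depth + 1):
        new_frontier = []
        for parent, pos, d in frontier:
            if gen == 1:
                dirs = [d]
            else:
                a = np.deg2rad(35.0)
                u = np.array([0.0, 1.0, 0.0])
                dirs = [np.cos(a) * d + np.sin(a) * u, np.cos(a) * d - np.sin(a) * u]
            for nd in dirs:
                nd = nd / np.linalg.norm(nd)
                end = pos + length * 0.8 ** (gen - 1) * nd
                pts = np.linspace(pos, end, 9)
                nodes[next_id] = end
                segments.append(Segment(parent, next_id, pts, np.full(9, 2.0)))
                new_frontier.append((next_id, end, nd))
                next_id += 1
        frontier = new_frontier
    return SpatialGraph(nodes, segments, inlet_node=0)


def small_phantom_spec(seed: int = 0) -> PhantomSpec:
    """Depth-3 phantom on a small grid: fast enough for unit tests."""
    return PhantomSpec(
        grid_shape=(100, 80, 80),
        voxel_spacing_mm=(0.66, 0.66, 0.66),
        tree_depth=3,
        root_radius_mm=4.0,
        segment_length_mm=14.0,
        seed=seed,
    )
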