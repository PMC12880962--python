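"""Spatial graph representation of a vessel network.

Nodes are branch points and vessel end points with world positions in mm;
segments are ordered polylines connecting two nodes, carrying a radius (mm)
at every polyline point.  This container is shared by the phantom generator
(which builds ground-truth graphs analytically) and the skeletonization
pipeline (which reconstructs graphs from binary masks), so morphometrics can
compare the two directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = ["Segment", "SpatialGraph"]

_ENDPOINT_TOL = 1e-6


@dataclass
class Segment:
    """One vessel segment: an ordered polyline between two nodes."""

    node_a: int
    node_b: int
    points: np.ndarray  # (n, 3) world mm
    radii_mm: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.radii_mm = np.asarray(self.radii_mm, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("segment points must have shape (n, 3)")
        if self.points.shape[0] < 2:
            raise ValueError("segment polyline needs at least 2 points")
        if self.radii_mm.shape != (self.points.shape[0],):
            raise ValueError("radii_mm must have one value per polyline point")
        if np.any(self.radii_mm < 0):
            raise ValueError("radii must be non-negative")

    @property
    def curved_length_mm(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def straight_length_mm(self) -> float:
        return float(np.linalg.norm(self.points[-1] - self.points[0]))

    def arclengths_mm(self) -> np.ndarray:
        """Cumulative arc length at each polyline point (starts at 0)."""
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate(([0.0], np.cumsum(steps)))


@dataclass
class SpatialGraph:
    """Vessel network: nodes (id -> world position) and polyline segments.

    ``inlet_node`` optionally designates the perfusion inlet (the portal-vein
    entry in the liver setting); path distances for bolus simulation and
    tracking are measured from it.
    """

    nodes: dict[int, np.ndarray]
    segments: list[Segment] = field(default_factory=list)
    inlet_node: int | None = None

    def __post_init__(self) -> None:
        self.nodes = {int(k): np.asarray(v, dtype=float) for k, v in self.nodes.items()}
        for seg in self.segments:
            for nid, end in ((seg.node_a, seg.points[0]), (seg.node_b, seg.points[-1])):
                if nid not in self.nodes:
                    raise ValueError(f"segment references unknown node {nid}")
                if np.linalg.norm(self.nodes[nid] - end) > 1e-3:
                    raise ValueError(
                        f"segment endpoint {end} does not coincide with node {nid} "
                        f"at {self.nodes[nid]}"
                    )
        if self.inlet_node is not None and self.inlet_node not in self.nodes:
            raise ValueError(f"inlet node {self.inlet_node} not in graph")

    # -- topology ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def degrees(self) -> dict[int, int]:
        """Node degree = number of incident segment ends (loops count twice)."""
        deg = {nid: 0 for nid in self.nodes}
        for seg in self.segments:
            deg[seg.node_a] += 1
            deg[seg.node_b] += 1
        return deg

    def terminal_nodes(self) -> list[int]:
        return [n for n, d in self.degrees().items() if d == 1]

    def branching_nodes(self) -> list[int]:
        return [n for n, d in self.degrees().items() if d >= 3]

    def to_networkx(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for nid, pos in self.nodes.items():
            g.add_node(nid, position=pos)
        for i, seg in enumerate(self.segments):
            g.add_edge(seg.node_a, seg.node_b, key=i, length=seg.curved_length_mm, segment=i)
        return g

    def path_distances_from_inlet(self) -> list[np.ndarray]:
        """Arc-length distance (mm) from the inlet to every polyline point.

        Returns one array per segment, aligned with the segment's points.
        Node-to-node distances follow shortest paths along the network with
        curved segment lengths as weights.
        """
        if self.inlet_node is None:
            raise ValueError("graph has no designated inlet node")
        g = self.to_networkx()
        node_dist = nx.shortest_path_length(g, source=self.inlet_node, weight="length")
        out = []
        for seg in self.segments:
            s = seg.arclengths_mm()
            length = s[-1]
            da = node_dist.get(seg.node_a, np.inf)
            db = node_dist.get(seg.node_b, np.inf)
            out.append(np.minimum(da + s, db + (length - s)))
        return out

    def inlet_to_leaf_path_points(self) -> np.ndarray:
        """Ordered polyline from the inlet to the farthest terminal node.

        Concatenates segment polylines along the (unique, in a tree)
        path from the inlet to the leaf with the greatest path distance —
        the natural centerline for bolus-front tracking.
        """
        if self.inlet_node is None:
            raise ValueError("graph has no designated inlet node")
        g = self.to_networkx()
        node_dist = nx.shortest_path_length(g, source=self.inlet_node, weight="length")
        leaves = [n for n, d in self.degrees().items() if d == 1 and n != self.inlet_node]
        if not leaves:
            leaves = [max(node_dist, key=node_dist.get)]
        target = max(leaves, key=lambda n: node_dist.get(n, -np.inf))
        node_path = nx.shortest_path(g, self.inlet_node, target, weight="length")
        pts: list[np.ndarray] = []
        for u, v in zip(node_path[:-1], node_path[1:]):
            candidates = [
                s
                for s in self.segments
                if {s.node_a, s.node_b} == {u, v}
            ]
            seg = min(candidates, key=lambda s: s.curved_length_mm)
            seg_pts = seg.points if seg.node_a == u else seg.points[::-1]
            pts.append(seg_pts if not pts else seg_pts[1:])
        return np.concatenate(pts, axis=0)

    # -- serialization ----------------------------------------------------

    def to_json(self, path=None) -> str:
        doc = {
            "nodes": [
                {"id": nid, "position_mm": list(map(float, pos))}
                for nid, pos in sorted(self.nodes.items())
            ],
            "segments": [
                {
                    "node_a": seg.node_a,
                    "node_b": seg.node_b,
                    "points_mm": seg.points.tolist(),
                    "radii_mm": seg.radii_mm.tolist(),
                }
                for seg in self.segments
            ],
            "inlet_node": self.inlet_node,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SpatialGraph":
        """Load from a JSON string or a file path."""
        if isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        nodes = {int(n["id"]): np.array(n["position_mm"]) for n in doc["nodes"]}
        segments = [
            Segment(
                int(s["node_a"]),
                int(s["node_b"]),
                np.array(s["points_mm"]),
                np.array(s["radii_mm"]),
            )
            for s in doc["segments"]
        ]
        inlet = doc.get("inlet_node")
        return cls(nodes, segments, inlet_node=None if inlet is None else int(inlet))

    def to_csv(self, path) -> None:
        """Per-segment edge list: id, nodes, lengths, mean radius, tortuosity."""
        import pandas as pd

        from .morphometrics import segment_metrics

        rows = []
        for i, seg in enumerate(self.segments):
            m = segment_metrics(seg)
            rows.append(
                {
                    "segment_id": i,
                    "node_a": seg.node_a,
                    "node_b": seg.node_b,
                    "curved_length_mm": m.curved_length_mm,
                    "straight_length_mm": m.straight_length_mm,
                    "tortuosity": m.tortuosity,
                    "mean_radius_mm": m.mean_radius_mm,
                    "volume_mm3": m.volume_mm3,
                }
            )
        pd.DataFrame(rows).to_csv(path, index=False)
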