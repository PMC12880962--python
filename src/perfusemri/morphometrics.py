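"""Vascular network morphometrics from a spatial graph.

Terminology follows the vascular-imaging convention: a *terminal node* has
degree 1, a *branching node* degree >= 3 (degree-2 cycle markers are counted
as neither), the *coordination number* of a branching node is its degree,
and *tortuosity* is curved (arc) length over straight (chord) length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graph import Segment, SpatialGraph

__all__ = ["SegmentMetrics", "NetworkSummary", "segment_metrics", "network_summary"]


@dataclass
class SegmentMetrics:
    curved_length_mm: float
    straight_length_mm: float
    tortuosity: float
    mean_radius_mm: float
    volume_mm3: float


@dataclass
class NetworkSummary:
    total_length_mm: float
    total_volume_mm3: float
    n_branching_nodes: int
    n_terminal_nodes: int
    terminal_fraction: float
    mean_coordination_number: float
    median_segment_length_mm: float
    median_radius_mm: float
    median_tortuosity: float
    segments: pd.DataFrame

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "segments"}
        return {k: (float(v) if isinstance(v, (np.floating, float)) else v) for k, v in d.items()}


def segment_metrics(segment: Segment) -> SegmentMetrics:
    """Length, tortuosity, mean radius and frustum volume of one segment.

    Volume is the sum over polyline intervals of ``pi * r_mean**2 * dl`` with
    ``r_mean`` the interval's mean radius.  Tortuosity is defined as 1 when
    the chord length is zero (closed-loop segments).
    """
    pts = segment.points
    if pts.shape[0] < 2:
        raise ValueError("segment polyline needs at least 2 points")
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    curved = float(steps.sum())
    straight = float(np.linalg.norm(pts[-1] - pts[0]))
    # closed loops have (numerically) zero chords: tortuosity defined as 1
    tortuosity = 1.0 if straight < 1e-9 else curved / straight
    r = segment.radii_mm
    r_mid = 0.5 * (r[:-1] + r[1:])
    volume = float(np.sum(np.pi * r_mid**2 * steps))
    return SegmentMetrics(curved, straight, tortuosity, float(r.mean()), volume)


def network_summary(graph: SpatialGraph) -> NetworkSummary:
    """Whole-network statistics: totals, node counts and segment medians.

    Medians interpolate linearly between order statistics (numpy default).
    ``terminal_fraction`` is terminal / (terminal + branching); the mean
    coordination number averages degree over branching nodes only, so a tree
    of pure bifurcations scores exactly 3.
    """
    if graph.n_segments == 0:
        raise ValueError("cannot summarise an empty graph")
    rows = []
    for i, seg in enumerate(graph.segments):
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
    table = pd.DataFrame(rows)
    degrees = graph.degrees()
    terminal = [n for n, d in degrees.items() if d == 1]
    branching = [n for n, d in degrees.items() if d >= 3]
    n_t, n_b = len(terminal), len(branching)
    coordination = (
        float(np.mean([degrees[n] for n in branching])) if branching else float("nan")
    )
    return NetworkSummary(
        total_length_mm=float(table["curved_length_mm"].sum()),
        total_volume_mm3=float(table["volume_mm3"].sum()),
        n_branching_nodes=n_b,
        n_terminal_nodes=n_t,
        terminal_fraction=n_t / (n_t + n_b) if (n_t + n_b) else float("nan"),
        mean_coordination_number=coordination,
        median_segment_length_mm=float(table["curved_length_mm"].median()),
        median_radius_mm=float(table["mean_radius_mm"].median()),
        median_tortuosity=float(table["tortuosity"].median()),
        segments=table,
    )
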