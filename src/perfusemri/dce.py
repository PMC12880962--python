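"""Semi-quantitative DCE-MRI analysis: TTP maps, ROI enhancement curves,
bolus-front tracking, and volumetric flow.

Enhancement is measured as signal difference from a pre-contrast baseline
(no conversion to gadolinium concentration).  Flow in a vessel of diameter
``d`` carrying fluid at velocity ``v`` is ``Q = (1/4) * pi * d**2 * v``;
with d in cm and v in cm/min, Q comes out in mL/min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import ImageVolume

__all__ = [
    "TTPMap",
    "EnhancementCurve",
    "FlowMeasurement",
    "ttp_map",
    "roi_enhancement_curve",
    "track_bolus_front",
    "estimate_velocity",
    "volumetric_flow",
]


@dataclass
class TTPMap:
    """Seconds from scan start to (first) maximal enhancement, per voxel."""

    values: np.ndarray
    valid: np.ndarray  # False where the voxel never enhances above the floor
    voxel_spacing_mm: tuple[float, float, float]
    frame_interval_s: float


@dataclass
class EnhancementCurve:
    times_s: np.ndarray
    mean_signal: np.ndarray
    min_signal: np.ndarray
    max_signal: np.ndarray
    roi_descriptor: dict

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.times_s) > 0) and self.times_s.size > 1:
            raise ValueError("times must be strictly increasing")
        if np.any(self.min_signal > self.mean_signal + 1e-9) or np.any(
            self.mean_signal > self.max_signal + 1e-9
        ):
            raise ValueError("min <= mean <= max must hold at every time point")


@dataclass
class FlowMeasurement:
    location_label: str
    diameter_cm: float
    velocity_cm_per_min: float
    flow_mL_per_min: float
    uncertainty_mL_per_min: float = 0.0


def ttp_map(
    vol4d: ImageVolume, baseline_frames: int = 1, noise_floor: float = 0.0
) -> TTPMap:
    """Voxel-wise time to peak enhancement.

    Enhancement is signal minus the mean over the first ``baseline_frames``
    frames; TTP is the frame interval times the index of the *first* frame
    attaining the maximum (deterministic tie rule, which on a step-shaped
    bolus equals the arrival frame).  Voxels whose peak enhancement does not
    exceed ``noise_floor`` are flagged invalid.
    """
    if not vol4d.is_4d:
        raise ValueError("ttp_map requires a 4D volume")
    n = vol4d.n_frames
    if n < 2 or not (0 < baseline_frames < n):
        raise ValueError(f"need >= 2 frames and 0 < baseline_frames < {n}")
    data = np.asarray(vol4d.values, dtype=float)
    baseline = data[..., :baseline_frames].mean(axis=-1)
    enh = data - baseline[..., None]
    peak = enh.max(axis=-1)
    first_max = np.argmax(enh == peak[..., None], axis=-1)
    valid = peak > noise_floor
    values = first_max * float(vol4d.frame_interval_s)
    values = np.where(valid, values, np.nan)
    return TTPMap(values, valid, vol4d.voxel_spacing_mm, float(vol4d.frame_interval_s))


def roi_enhancement_curve(
    vol4d: ImageVolume,
    roi_centers: list[tuple[int, int, int]],
    roi_size: int = 10,
    vessel_mask: ImageVolume | None = None,
) -> EnhancementCurve:
    """Mean/min/max signal envelope over repeat in-plane ROIs.

    Each repeat is a ``roi_size x roi_size`` square of voxels in the x-y
    plane at the centre's z slice.  ROIs must lie fully inside the grid and,
    when a vessel mask is given, entirely within the vessel — a repeat that
    crosses the boundary raises an error naming it.
    """
    if not vol4d.is_4d:
        raise ValueError("roi_enhancement_curve requires a 4D volume")
    data = np.asarray(vol4d.values, dtype=float)
    nx, ny, nz, _ = data.shape
    half_lo = roi_size // 2
    curves = []
    for r, center in enumerate(roi_centers):
        cx, cy, cz = (int(c) for c in center)
        x0, y0 = cx - half_lo, cy - half_lo
        x1, y1 = x0 + roi_size, y0 + roi_size
        if x0 < 0 or y0 < 0 or x1 > nx or y1 > ny or not (0 <= cz < nz):
            raise ValueError(f"repeat {r}: ROI at {center} extends outside the grid")
        if vessel_mask is not None:
            vm = np.asarray(vessel_mask.values, dtype=bool)
            if not vm[x0:x1, y0:y1, cz].all():
                raise ValueError(
                    f"repeat {r}: ROI at {center} is not entirely within the vessel mask"
                )
        curves.append(data[x0:x1, y0:y1, cz, :].mean(axis=(0, 1)))
    stack = np.vstack(curves)
    return EnhancementCurve(
        times_s=vol4d.frame_times_s(),
        mean_signal=stack.mean(axis=0),
        min_signal=stack.min(axis=0),
        max_signal=stack.max(axis=0),
        roi_descriptor={"centers": [tuple(c) for c in roi_centers], "size": roi_size},
    )


def track_bolus_front(
    vol4d: ImageVolume,
    path_points_mm: np.ndarray,
    threshold_fraction: float = 0.5,
    baseline_frames: int = 1,
) -> list[tuple[float, float]]:
    """Bolus-front position along a centerline path, per frame.

    For each ordered path point the arrival frame is the first frame whose
    enhancement reaches ``threshold_fraction`` of that point's eventual
    maximum enhancement.  The front position at a frame is the arc-length
    distance (cm) of the farthest point that has arrived; positions are
    non-decreasing by construction of a cumulative maximum.  Raises when no
    point ever crosses its threshold.
    """
    if not (0 < threshold_fraction < 1):
        raise ValueError("threshold_fraction must lie in (0, 1)")
    if not vol4d.is_4d:
        raise ValueError("track_bolus_front requires a 4D volume")
    pts = np.asarray(path_points_mm, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
        raise ValueError("path needs >= 2 points of shape (n, 3)")
    arclen_cm = np.concatenate(
        ([0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    ) / 10.0

    idx = np.round(vol4d.world_to_voxel(pts)).astype(int)
    idx = np.clip(idx, 0, np.asarray(vol4d.spatial_shape) - 1)
    series = np.asarray(vol4d.values, dtype=float)[tuple(idx.T)]  # (n_points, n_frames)
    baseline = series[:, :baseline_frames].mean(axis=1, keepdims=True)
    enh = series - baseline
    peak = enh.max(axis=1)
    enhancing = peak > 0
    if not enhancing.any():
        raise ValueError("no path point ever crosses its enhancement threshold")
    arrived = enh >= (threshold_fraction * peak)[:, None]
    arrived[~enhancing, :] = False

    times = vol4d.frame_times_s()
    front = []
    best = 0.0
    for k in range(series.shape[1]):
        which = np.nonzero(arrived[:, k])[0]
        if which.size:
            best = max(best, float(arclen_cm[which.max()]))
        front.append((float(times[k]), best))
    return front


def estimate_velocity(front: list[tuple[float, float]]) -> tuple[float, float]:
    """Bolus speed from the front trajectory: slope of distance vs time.

    Returns (velocity in cm/min, SD over per-interval speeds).  A least
    squares line is fitted through the *advancing window* of the trajectory
    — from the last sample before the front starts moving to the first
    sample at which it reaches its final position — so the plateaus before
    bolus entry and after it has traversed the whole path do not bias the
    slope.  A front that never moves gives 0 cm/min.
    """
    if len(front) < 2:
        raise ValueError("need at least two front samples")
    t = np.array([f[0] for f in front], dtype=float)
    d = np.array([f[1] for f in front], dtype=float)
    if np.ptp(t) == 0:
        raise ValueError("front samples must span more than one time point")
    moving = np.nonzero(d > d[0])[0]
    k_start = max(moving[0] - 1, 0) if moving.size else 0
    at_end = np.nonzero(d >= d[-1])[0]
    k_end = at_end[0] if at_end.size else len(d) - 1
    if k_end - k_start >= 2:
        # the sample where the front reaches its final position only bounds
        # the true arrival between frames (interval-censored); drop it when
        # enough uncensored samples remain
        k_end -= 1
    if k_end > k_start:
        t, d = t[k_start : k_end + 1], d[k_start : k_end + 1]
    slope = np.polyfit(t, d, 1)[0]  # cm/s
    dt = np.diff(t)
    speeds = np.diff(d)[dt > 0] / dt[dt > 0] * 60.0
    sd = float(np.std(speeds, ddof=1)) if speeds.size > 1 else 0.0
    return float(slope * 60.0), sd


def volumetric_flow(diameter_cm: float, velocity_cm_per_min: float) -> float:
    """Volumetric flow Q = (1/4) * pi * d^2 * v (cm, cm/min -> mL/min)."""
    if diameter_cm < 0 or velocity_cm_per_min < 0:
        raise ValueError("diameter and velocity must be non-negative")
    return 0.25 * np.pi * diameter_cm**2 * velocity_cm_per_min
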