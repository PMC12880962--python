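"""Apparent diffusion coefficient (ADC) mapping from multi-b DWI.

The signal model is the monoexponential decay ``S = S0 * exp(-D * b)``; D is
estimated per voxel by log-linear least squares (exact on noise-free input),
fitted independently for each diffusion-encoding direction and averaged
arithmetically across directions.  Units: b in s/mm², D in mm²/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import ImageVolume

__all__ = ["DiffusionFit", "ADCMap", "fit_adc_voxel", "compute_adc_map", "parenchyma_stats"]


@dataclass
class DiffusionFit:
    """Per-voxel monoexponential fit result."""

    S0: float
    D: float  # mm^2/s, clipped at 0
    residual: float  # RMS of log-signal residuals
    valid: bool = True
    negative_D: bool = False


@dataclass
class ADCMap:
    """Voxel-wise ADC in mm²/s with per-direction maps and a validity mask."""

    values: np.ndarray
    direction_maps: dict[int, np.ndarray]
    valid: np.ndarray  # False where the fit was impossible (non-positive signal)
    voxel_spacing_mm: tuple[float, float, float]


def _loglinear(signals: np.ndarray, b: np.ndarray):
    """Slope/intercept of ln S on b; returns (S0, D, rms)."""
    y = np.log(signals)
    bm = b.mean()
    ym = y.mean()
    slope = float(((b - bm) @ (y - ym)) / ((b - bm) @ (b - bm)))
    intercept = ym - slope * bm
    resid = y - (intercept + slope * b)
    return float(np.exp(intercept)), -slope, float(np.sqrt(np.mean(resid**2)))


def fit_adc_voxel(signals, b_values) -> DiffusionFit:
    """Fit S0 and D for one voxel's signals across b-values.

    Requires at least two distinct b-values and strictly positive signals
    (the log transform is undefined otherwise — such voxels are returned
    flagged invalid rather than raising).  Negative fitted D (noise) is
    clipped to 0 and flagged.
    """
    b = np.asarray(b_values, dtype=float)
    s = np.asarray(signals, dtype=float)
    if b.shape != s.shape or b.size < 2 or len(set(b.tolist())) < 2:
        raise ValueError("need matching signals for >= 2 distinct b-values")
    if np.any(s <= 0):
        return DiffusionFit(S0=np.nan, D=np.nan, residual=np.nan, valid=False)
    S0, D, rms = _loglinear(s, b)
    if D < 0:
        return DiffusionFit(S0=S0, D=0.0, residual=rms, negative_D=True)
    return DiffusionFit(S0=S0, D=D, residual=rms)


def compute_adc_map(dwi: dict[int, dict[float, ImageVolume]]) -> ADCMap:
    """Voxel-wise ADC from per-direction, per-b volumes.

    ``dwi[direction][b]`` gives the volume for that encoding.  Every
    direction must share the same b-values and geometry; D is fitted
    log-linearly per direction and the direction maps averaged.
    """
    if not dwi:
        raise ValueError("no DWI volumes supplied")
    directions = sorted(dwi)
    b_ref = sorted(dwi[directions[0]])
    missing = [d for d in directions if sorted(dwi[d]) != b_ref]
    if missing or len(b_ref) < 2:
        raise ValueError(
            f"directions {missing} missing b-values (reference set {b_ref})"
            if missing
            else "need >= 2 b-values"
        )
    shape = dwi[directions[0]][b_ref[0]].spatial_shape
    spacing = dwi[directions[0]][b_ref[0]].voxel_spacing_mm
    b = np.asarray(b_ref, dtype=float)
    bc = b - b.mean()
    denom = float(bc @ bc)

    direction_maps: dict[int, np.ndarray] = {}
    valid = np.ones(shape, dtype=bool)
    for d in directions:
        stack = np.stack([np.asarray(dwi[d][bv].values, dtype=float) for bv in b_ref], axis=-1)
        if stack.shape[:-1] != shape:
            raise ValueError(f"direction {d}: geometry mismatch")
        ok = np.all(stack > 0, axis=-1)
        valid &= ok
        y = np.where(stack > 0, np.log(np.where(stack > 0, stack, 1.0)), 0.0)
        ym = y.mean(axis=-1, keepdims=True)
        slope = ((y - ym) @ bc) / denom
        D = np.clip(-slope, 0.0, None)
        D[~ok] = np.nan
        direction_maps[d] = D
    mean_map = np.mean(np.stack(list(direction_maps.values())), axis=0)
    return ADCMap(mean_map, direction_maps, valid, spacing)


def parenchyma_stats(
    adc: ADCMap,
    bmin_volume: ImageVolume,
    vessel_mask: ImageVolume | None = None,
    background_threshold: float | None = None,
    bins: int = 64,
):
    """Mean, SD and histogram of parenchymal ADC.

    Voxels are included when the lowest-b signal exceeds the background
    threshold (default: 10% of that volume's robust maximum, the 99th
    percentile) AND they fall outside the binary vessel mask AND their fit is
    valid.  Raises when nothing remains.
    """
    bmin = np.asarray(bmin_volume.values, dtype=float)
    if bmin.shape != adc.values.shape:
        raise ValueError("b-min volume geometry does not match the ADC map")
    if background_threshold is None:
        background_threshold = 0.1 * float(np.percentile(bmin, 99))
    include = (bmin > background_threshold) & adc.valid
    if vessel_mask is not None:
        vm = np.asarray(vessel_mask.values, dtype=bool)
        if vm.shape != adc.values.shape:
            raise ValueError("vessel mask geometry does not match the ADC map")
        include &= ~vm
    values = adc.values[include]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("no voxels left after background and vessel masking")
    hist, edges = np.histogram(values, bins=bins)
    return float(values.mean()), float(values.std()), (hist, edges)
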