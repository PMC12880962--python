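"""Seeded region-growing vessel segmentation ("magic wand" style).

A voxel joins the mask when it is connected to a seed through voxels whose
intensity lies inside an absolute [low, high] band.  The band is explicit
rather than a seed-relative tolerance so runs are reproducible.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .volume import ImageVolume

__all__ = ["BinaryMask", "region_grow", "merge_masks"]


# A binary mask is simply an ImageVolume with boolean values; this alias is
# used in signatures for readability.
BinaryMask = ImageVolume

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    26: ndimage.generate_binary_structure(3, 3),
}


def region_grow(
    vol: ImageVolume,
    seeds: list[tuple[int, int, int]],
    low: float,
    high: float,
    connectivity: int = 26,
) -> BinaryMask:
    """Flood-fill from seeds through voxels with intensity in [low, high].

    Returns the union of the in-band connected components that contain at
    least one seed.  Seeds whose own intensity is outside the band are
    skipped with a warning; out-of-bounds seeds raise.
    """
    if low > high:
        raise ValueError(f"low ({low}) must not exceed high ({high})")
    if connectivity not in _STRUCTS:
        raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")
    data = np.asarray(vol.values)
    if data.ndim != 3:
        raise ValueError("region_grow expects a 3D volume")

    shape = data.shape
    valid_seeds = []
    for seed in seeds:
        seed = tuple(int(c) for c in seed)
        if len(seed) != 3 or any(c < 0 or c >= n for c, n in zip(seed, shape)):
            raise ValueError(f"seed {seed} out of bounds for shape {shape}")
        if not (low <= data[seed] <= high):
            warnings.warn(
                f"seed {seed} has value {data[seed]} outside [{low}, {high}]; skipped",
                stacklevel=2,
            )
            continue
        valid_seeds.append(seed)

    band = (data >= low) & (data <= high)
    out = np.zeros(shape, dtype=bool)
    if valid_seeds:
        labels, _ = ndimage.label(band, structure=_STRUCTS[connectivity])
        keep = {labels[s] for s in valid_seeds} - {0}
        if keep:
            out = np.isin(labels, sorted(keep))
    if not out.any():
        warnings.warn("region growing produced an empty mask", stacklevel=2)
    return ImageVolume(out, vol.voxel_spacing_mm, origin_mm=vol.origin_mm)


def merge_masks(masks: list[BinaryMask]) -> BinaryMask:
    """Voxel-wise union of segmentations (e.g. per-plane passes)."""
    if not masks:
        raise ValueError("merge_masks needs at least one mask")
    first = masks[0]
    out = np.zeros(first.spatial_shape, dtype=bool)
    for m in masks:
        if m.spatial_shape != first.spatial_shape or not np.allclose(
            m.voxel_spacing_mm, first.voxel_spacing_mm
        ):
            raise ValueError(
                "mask geometry mismatch: "
                f"{m.spatial_shape}/{m.voxel_spacing_mm} vs "
                f"{first.spatial_shape}/{first.voxel_spacing_mm}"
            )
        out |= np.asarray(m.values, dtype=bool)
    return ImageVolume(out, first.voxel_spacing_mm, origin_mm=first.origin_mm)
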