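"""Volumetric image container and shared geometry operations.

An :class:`ImageVolume` is a 3D ``(x, y, z)`` or 4D ``(x, y, z, t)`` scalar
grid with physical voxel spacing in millimetres and, for time series, a frame
interval in seconds.  The world position of voxel ``(i, j, k)`` is
``origin_mm + (index + 0.5) * voxel_spacing_mm`` — voxel indices are 0-based
and refer to voxel *centres*.  All graph geometry downstream is expressed in
these world-millimetre coordinates.

Volumes round-trip through NIfTI-1; the time axis is stored as the 4th
dimension with the frame interval in the time-spacing header field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "read_volume",
    "write_volume",
    "resample_isotropic",
    "mip_over_time",
]


@dataclass
class ImageVolume:
    """A 3D or 4D scalar grid with physical geometry.

    Parameters
    ----------
    values
        Array of shape ``(nx, ny, nz)`` or ``(nx, ny, nz, nt)``.
    voxel_spacing_mm
        Per-axis spacing for the three spatial axes, in mm.  All positive.
    frame_interval_s
        Seconds between frames; required for 4D volumes, ignored for 3D.
    origin_mm
        World offset of the grid corner (voxel ``(0,0,0)`` centre sits at
        ``origin + 0.5 * spacing``).
    """

    values: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]
    frame_interval_s: float | None = None
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim not in (3, 4):
            raise ValueError(f"values must be 3D or 4D, got {self.values.ndim}D")
        self.voxel_spacing_mm = tuple(float(s) for s in self.voxel_spacing_mm)
        if len(self.voxel_spacing_mm) != 3:
            raise ValueError("voxel_spacing_mm must have three entries")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError(f"voxel_spacing_mm must be positive, got {self.voxel_spacing_mm}")
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if self.is_4d:
            if self.frame_interval_s is None:
                raise ValueError("4D volumes require frame_interval_s")
            if not (self.frame_interval_s > 0):
                raise ValueError(f"frame_interval_s must be positive, got {self.frame_interval_s}")

    # -- geometry helpers -------------------------------------------------

    @property
    def is_4d(self) -> bool:
        return self.values.ndim == 4

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def n_frames(self) -> int:
        if not self.is_4d:
            raise ValueError("n_frames is only defined for 4D volumes")
        return self.values.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.values.shape[:3]

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical size of the grid along each spatial axis."""
        return tuple(n * s for n, s in zip(self.spatial_shape, self.voxel_spacing_mm))

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """World-mm position of voxel centre(s); ``idx`` is (..., 3)."""
        idx = np.asarray(idx, dtype=float)
        spacing = np.asarray(self.voxel_spacing_mm)
        return np.asarray(self.origin_mm) + (idx + 0.5) * spacing

    def world_to_voxel(self, pos: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`voxel_to_world` (fractional indices)."""
        pos = np.asarray(pos, dtype=float)
        spacing = np.asarray(self.voxel_spacing_mm)
        return (pos - np.asarray(self.origin_mm)) / spacing - 0.5

    def frame_times_s(self) -> np.ndarray:
        """Acquisition time of each frame, starting at 0 s."""
        return np.arange(self.n_frames) * float(self.frame_interval_s)

    def with_values(self, values: np.ndarray) -> "ImageVolume":
        """Copy of this volume's geometry holding different values."""
        return replace(self, values=values)


# -- NIfTI I/O -------------------------------------------------------------


def write_volume(vol: ImageVolume, path) -> None:
    """Write a volume to NIfTI-1 (``.nii`` or ``.nii.gz``)."""
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = vol.voxel_spacing_mm
    affine[:3, 3] = vol.origin_mm
    data = np.asarray(vol.values)
    if data.dtype == bool:
        data = data.astype(np.uint8)  # NIfTI has no boolean type
    img = nib.Nifti1Image(data, affine)
    zooms = list(vol.voxel_spacing_mm)
    if vol.is_4d:
        zooms.append(float(vol.frame_interval_s))
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, str(path))


def read_volume(path) -> ImageVolume:
    """Read a NIfTI volume written by :func:`write_volume` (or compatible)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim not in (3, 4):
        raise ValueError(f"{path}: expected 3D or 4D data, got {data.ndim}D")
    zooms = img.header.get_zooms()
    spacing = tuple(float(z) for z in zooms[:3])
    if any(s <= 0 for s in spacing):
        raise ValueError(f"{path}: non-positive voxel spacing in header: {spacing}")
    frame_interval = None
    if data.ndim == 4:
        frame_interval = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else None
        if frame_interval is None:
            raise ValueError(f"{path}: 4D volume with non-positive frame interval in header")
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return ImageVolume(data, spacing, frame_interval_s=frame_interval, origin_mm=origin)


# -- resampling ------------------------------------------------------------


def _mitchell_kernel(x: np.ndarray, B: float = 1.0 / 3.0, C: float = 1.0 / 3.0) -> np.ndarray:
    """Mitchell–Netravali cubic BC-kernel; the B = C = 1/3 'Mitchell' setting."""
    x = np.abs(x)
    x2, x3 = x * x, x * x * x
    out = np.zeros_like(x)
    m1 = x < 1
    out[m1] = (
        (12 - 9 * B - 6 * C) * x3[m1]
        + (-18 + 12 * B + 6 * C) * x2[m1]
        + (6 - 2 * B)
    ) / 6.0
    m2 = (x >= 1) & (x < 2)
    out[m2] = (
        (-B - 6 * C) * x3[m2]
        + (6 * B + 30 * C) * x2[m2]
        + (-12 * B - 48 * C) * x[m2]
        + (8 * B + 24 * C)
    ) / 6.0
    return out


def _linear_kernel(x: np.ndarray) -> np.ndarray:
    return np.clip(1.0 - np.abs(x), 0.0, None)


_KERNELS = {
    "mitchell": (_mitchell_kernel, 2),
    "linear": (_linear_kernel, 1),
}


def _axis_weight_matrix(n_in: int, n_out: int, scale: float, method: str) -> np.ndarray:
    """Dense (n_out, n_in) interpolation weights for one axis.

    ``scale`` = spacing_out / spacing_in.  Output sample j sits at input
    fractional index ``(j + 0.5) * scale - 0.5``.  Border samples clamp to the
    edge and weights are renormalised so constants are reproduced exactly.
    """
    centers = (np.arange(n_out) + 0.5) * scale - 0.5
    if method == "nearest":
        W = np.zeros((n_out, n_in))
        idx = np.clip(np.round(centers).astype(int), 0, n_in - 1)
        W[np.arange(n_out), idx] = 1.0
        return W
    kernel, support = _KERNELS[method]
    # widen the footprint when downsampling (anti-aliasing)
    width = max(scale, 1.0)
    half = int(np.ceil(support * width))
    offsets = np.arange(-half, half + 1)
    idx = np.floor(centers)[:, None] + offsets[None, :]
    w = kernel((idx - centers[:, None]) / width)
    idx = np.clip(idx.astype(int), 0, n_in - 1)
    w_sum = w.sum(axis=1, keepdims=True)
    w = w / np.where(w_sum == 0, 1.0, w_sum)
    W = np.zeros((n_out, n_in))
    np.add.at(W, (np.repeat(np.arange(n_out), idx.shape[1]), idx.ravel()), w.ravel())
    return W


def resample_isotropic(
    vol: ImageVolume, target_spacing_mm: float, method: str = "mitchell"
) -> ImageVolume:
    """Resample a volume to isotropic voxels of ``target_spacing_mm``.

    All three spatial axes are resampled (anisotropy along any axis is
    handled, not only the slice direction).  The grid's physical extent is
    preserved to within one voxel.  ``method`` is one of ``mitchell``
    (Mitchell–Netravali cubic, B = C = 1/3), ``linear`` or ``nearest``.
    A 4D volume is resampled frame by frame; the time axis is untouched.
    """
    target = float(target_spacing_mm)
    if target <= 0:
        raise ValueError(f"target_spacing_mm must be positive, got {target}")
    if method not in ("mitchell", "linear", "nearest"):
        raise ValueError(f"unknown method {method!r}; expected mitchell, linear or nearest")
    if any(target > e for e in vol.extent_mm):
        raise ValueError(
            f"target spacing {target} mm exceeds grid extent {vol.extent_mm} mm"
        )
    out_shape = tuple(
        max(1, int(round(e / target))) for e in vol.extent_mm
    )
    data = np.asarray(vol.values, dtype=float)
    for axis in range(3):
        n_in = data.shape[axis]
        n_out = out_shape[axis]
        scale = target / vol.voxel_spacing_mm[axis]
        if n_out == n_in and abs(scale - 1.0) < 1e-12:
            continue
        W = _axis_weight_matrix(n_in, n_out, scale, method)
        data = np.moveaxis(np.tensordot(W, np.moveaxis(data, axis, 0), axes=(1, 0)), 0, axis)
    return ImageVolume(
        data,
        (target, target, target),
        frame_interval_s=vol.frame_interval_s,
        origin_mm=vol.origin_mm,
    )


def mip_over_time(vol4d: ImageVolume) -> ImageVolume:
    """Maximum intensity projection through the time dimension.

    Collapses a 4D series into a 3D volume where each voxel takes its maximum
    over frames — applied to binary contrast labels this yields the union
    mask of the perfused vascular network.
    """
    if not vol4d.is_4d:
        raise ValueError("mip_over_time requires a 4D volume")
    return ImageVolume(
        vol4d.values.max(axis=3),
        vol4d.voxel_spacing_mm,
        origin_mm=vol4d.origin_mm,
    )
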