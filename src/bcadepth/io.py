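"""Volume/mask containers, NIfTI I/O and isotropic resampling.

The pipeline operates on 3D scalar grids with physical voxel spacing in
millimetres.  Volumes and masks are exchanged as NIfTI-1 files; spacing is
taken from the header ``pixdim`` fields and the origin from the affine
translation.  Axis order is fixed as (x, y, z) with 0-based integer voxel
indices throughout the package.

Thickness and invasion-depth computations run on a 1 mm isotropic grid;
:func:`resample_isotropic` converts between acquisition and isotropic grids
(linear interpolation for intensities, nearest-neighbour for masks so labels
stay binary).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = ["Volume", "Mask", "read_volume", "write_volume", "read_mask",
           "write_mask", "resample_isotropic"]


@dataclass
class Volume:
    """A 3D scalar image with physical voxel spacing and origin (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.data.ndim}D")
        if min(self.data.shape) < 1:
            raise ValueError("every axis must have length >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must be length-3")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff


@dataclass
class Mask(Volume):
    """A binary (uint8, values in {0, 1}) label volume on the same grid."""

    def __post_init__(self) -> None:
        super().__post_init__()
        data = np.asarray(self.data)
        uniq = np.unique(data)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError(f"mask values must be in {{0, 1}}, got {uniq[:10]}")
        self.data = data.astype(np.uint8)

    def bool(self) -> np.ndarray:
        return self.data.astype(bool)

    @classmethod
    def from_bool(cls, data: np.ndarray, like: Volume | None = None) -> "Mask":
        spacing = like.spacing if like is not None else (1.0, 1.0, 1.0)
        origin = like.origin if like is not None else (0.0, 0.0, 0.0)
        return cls(np.asarray(data, dtype=bool).astype(np.uint8), spacing, origin)


def _read(path, cls):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D image, got {data.ndim}D in {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return cls(data, spacing, origin)


def read_volume(path) -> Volume:
    """Read a 3D NIfTI volume; spacing/origin come from the header."""
    return _read(path, Volume)


def read_mask(path) -> Mask:
    """Read a 3D NIfTI binary mask (values must be 0/1)."""
    return _read(path, Mask)


def write_volume(v: Volume, path) -> None:
    """Write a Volume (or Mask) as NIfTI-1; masks are stored as uint8."""
    data = v.data
    if isinstance(v, Mask):
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, v.affine())
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))


write_mask = write_volume


def resample_isotropic(v: Volume, target_mm: float = 1.0, order: int | None = None) -> Volume:
    """Resample to an isotropic grid of ``target_mm`` voxels.

    Output shape per axis is round(n_i * s_i / target_mm) (physical extent
    preserved to within one voxel).  Intensities use linear interpolation
    (order 1); masks use nearest-neighbour (order 0) and are re-binarized,
    unless ``order`` overrides the default.
    """
    if target_mm <= 0:
        raise ValueError(f"target_mm must be positive, got {target_mm}")
    is_mask = isinstance(v, Mask)
    if order is None:
        order = 0 if is_mask else 1
    if all(abs(s - target_mm) < 1e-12 for s in v.spacing):
        return replace(v, data=v.data.copy())
    out_shape = tuple(max(1, int(round(n * s / target_mm)))
                      for n, s in zip(v.data.shape, v.spacing))
    zoom = [o / n for o, n in zip(out_shape, v.data.shape)]
    data = ndimage.zoom(v.data.astype(float), zoom, order=order, mode="nearest",
                        grid_mode=True)
    spacing = (target_mm,) * 3
    if is_mask:
        return Mask((data > 0.5).astype(np.uint8), spacing, v.origin)
    return Volume(data, spacing, v.origin)
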