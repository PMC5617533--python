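"""Core image containers and NIfTI I/O.

The analysis operates on 3D scalar fields (PET SUV volumes, DWI signal
volumes, MR parameter maps) together with binary volumes of interest (VOI)
drawn on the same voxel grid.  Physical geometry is carried as the voxel
spacing in millimetres; all sphere/volume computations use voxel-centre
coordinates in physical space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import nibabel as nib
import numpy as np

#: Recognised modality tags.
MODALITIES = ("PET_SUV", "MR", "DWI")


@dataclass
class ImageVolume:
    """A 3D scalar field with physical voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar voxel values (SUV in g/mL for PET, arbitrary signal units
        for MR/DWI).
    spacing_mm : tuple of float
        Voxel spacing along each axis in millimetres; all entries > 0.
    modality : str
        One of ``PET_SUV``, ``MR``, ``DWI``.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    modality: str = "PET_SUV"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing_mm}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass
class VoiMask:
    """A binary mask aligned voxel-for-voxel with an :class:`ImageVolume`."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={self.data.ndim}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def check_alignment(self, volume: ImageVolume) -> None:
        if self.shape != volume.shape:
            raise ValueError(
                f"mask shape {self.shape} does not match volume shape {volume.shape}"
            )


def sphere_mask(
    shape: tuple[int, int, int],
    spacing_mm: Iterable[float],
    center_voxel: Iterable[float],
    radius_mm: float,
) -> np.ndarray:
    """Boolean mask of voxels whose centres lie within ``radius_mm`` of a point.

    ``center_voxel`` is given in (possibly fractional) voxel coordinates;
    distances are measured in physical millimetres.  Voxel membership by
    voxel-centre geometry makes voxel counts exactly enumerable.
    """
    spacing = np.asarray(tuple(spacing_mm), dtype=float)
    center = np.asarray(tuple(center_voxel), dtype=float)
    grids = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    d2 = sum(((g - c) * s) ** 2 for g, c, s in zip(grids, center, spacing))
    return d2 <= radius_mm**2


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def save_volume(volume: ImageVolume, path: str | Path) -> None:
    """Write a volume to NIfTI; spacing is stored in the affine diagonal."""
    affine = np.diag(list(volume.spacing_mm) + [1.0])
    nib.save(nib.Nifti1Image(volume.data.astype(np.float32), affine), str(path))


def load_volume(path: str | Path, modality: str = "PET_SUV") -> ImageVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(data=data, spacing_mm=spacing, modality=modality)


def save_mask(mask: VoiMask, spacing_mm: Iterable[float], path: str | Path) -> None:
    affine = np.diag(list(spacing_mm) + [1.0])
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), affine), str(path))


def load_mask(path: str | Path) -> VoiMask:
    img = nib.load(str(path))
    return VoiMask(data=np.asanyarray(img.dataobj) > 0)


def save_series(data4d: np.ndarray, spacing_mm: Iterable[float], path: str | Path) -> None:
    """Write a 4D dynamic series (x, y, z, t)."""
    affine = np.diag(list(spacing_mm) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data4d, dtype=np.float32), affine), str(path))


def load_series(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing
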