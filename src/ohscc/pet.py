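"""Metabolic tumor segmentation and conventional PET parameters.

The metabolic tumor is delineated inside a generously drawn VOI either with
a fixed SUV threshold (voxels with SUV strictly > 2.5) or with an adaptive,
background-referenced threshold T = bg + f * (SUVmax - bg), where the
background is the mean uptake of a 10-mm sphere placed in a lesion-free
region.  From the segmented tumor the conventional parameters follow:
SUVmax, SUVmean, metabolic tumor volume MTV (mL) and total lesion
glycolysis TLG = SUVmean x MTV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import ImageVolume, VoiMask, sphere_mask

FIXED_SUV_THRESHOLD = 2.5
ADAPTIVE_FRACTION = 0.5
BACKGROUND_SPHERE_DIAMETER_MM = 10.0


@dataclass
class ConventionalPetFeatures:
    """SUVmax/SUVmean (g/mL), MTV (mL) and TLG (g/mL x mL) for one lesion."""

    suv_max: float
    suv_mean: float
    mtv_ml: float
    tlg: float
    #: metadata: how the tumor mask was obtained
    segmentation: dict | None = None


def _require_pet(volume: ImageVolume) -> None:
    if volume.modality != "PET_SUV":
        raise ValueError(f"expected a PET_SUV volume, got modality {volume.modality!r}")


def keep_largest_component(mask: VoiMask) -> VoiMask:
    """Retain only the largest 26-connected component of a binary mask.

    Guards against disjoint physiologic-uptake specks picked up inside a
    generous VOI.  Off by default in the segmentation ops.
    """
    structure = np.ones((3, 3, 3), dtype=bool)
    labels, n = ndimage.label(mask.data, structure=structure)
    if n <= 1:
        return mask
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return VoiMask(labels == counts.argmax())


def segment_fixed_threshold(
    volume: ImageVolume,
    voi: VoiMask,
    threshold: float = FIXED_SUV_THRESHOLD,
    largest_component_only: bool = False,
) -> VoiMask:
    """Voxels inside the VOI with SUV strictly above ``threshold``.

    An empty result is returned (with a warning) rather than raised, so the
    caller can decide how to treat lesions without supra-threshold uptake.
    """
    _require_pet(volume)
    voi.check_alignment(volume)
    if voi.n_voxels == 0:
        raise ValueError("VOI is empty")
    mask = VoiMask(voi.data & (volume.data > threshold))
    if largest_component_only:
        mask = keep_largest_component(mask)
    if mask.n_voxels == 0:
        warnings.warn(
            f"no voxels above SUV {threshold} inside the VOI; returning empty mask",
            stacklevel=2,
        )
    return mask


def estimate_background(
    volume: ImageVolume,
    center: tuple[float, float, float],
    diameter_mm: float = BACKGROUND_SPHERE_DIAMETER_MM,
) -> float:
    """Mean SUV of a sphere of ``diameter_mm`` placed at ``center`` (voxels).

    The sphere must fit entirely inside the grid (voxel-centre geometry);
    it stands in for the lower-neck reference region used to anchor the
    adaptive threshold.
    """
    _require_pet(volume)
    radius = diameter_mm / 2.0
    for ax, (c, s, n) in enumerate(zip(center, volume.spacing_mm, volume.shape)):
        if c - radius / s < -0.5 or c + radius / s > n - 0.5:
            raise ValueError(
                f"background sphere (d={diameter_mm} mm) extends outside the grid "
                f"along axis {ax}"
            )
    mask = sphere_mask(volume.shape, volume.spacing_mm, center, radius)
    if not mask.any():
        raise ValueError("background sphere contains no voxel centres")
    return float(volume.data[mask].mean())


def segment_adaptive(
    volume: ImageVolume,
    voi: VoiMask,
    background: float,
    fraction: float = ADAPTIVE_FRACTION,
    largest_component_only: bool = False,
) -> VoiMask:
    """Background-referenced adaptive segmentation.

    Threshold T = background + fraction * (SUVmax_in_VOI - background);
    voxels with SUV strictly above T are kept.  Raises when the VOI shows
    no contrast over the background (SUVmax <= background).
    """
    _require_pet(volume)
    voi.check_alignment(volume)
    if not (0 < fraction < 1):
        raise ValueError("fraction must lie strictly between 0 and 1")
    if voi.n_voxels == 0:
        raise ValueError("VOI is empty")
    suv_max = float(volume.data[voi.data].max())
    if suv_max <= background:
        raise ValueError(
            f"no lesion contrast: SUVmax in VOI ({suv_max:.3g}) does not exceed "
            f"background ({background:.3g})"
        )
    threshold = background + fraction * (suv_max - background)
    mask = VoiMask(voi.data & (volume.data > threshold))
    if largest_component_only:
        mask = keep_largest_component(mask)
    return mask


def conventional_features(volume: ImageVolume, tumor_mask: VoiMask) -> ConventionalPetFeatures:
    """SUVmax, SUVmean, MTV and TLG over the segmented tumor.

    MTV = voxel count x voxel volume / 1000 (mL); TLG = SUVmean x MTV.
    """
    _require_pet(volume)
    tumor_mask.check_alignment(volume)
    if tumor_mask.n_voxels == 0:
        raise ValueError("tumor mask is empty; nothing to measure")
    vals = volume.data[tumor_mask.data]
    mtv_ml = tumor_mask.n_voxels * volume.voxel_volume_mm3 / 1000.0
    suv_mean = float(vals.mean())
    return ConventionalPetFeatures(
        suv_max=float(vals.max()),
        suv_mean=suv_mean,
        mtv_ml=mtv_ml,
        tlg=suv_mean * mtv_ml,
    )
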