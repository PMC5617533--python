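"""Intratumor heterogeneity: NGLCM and NGTDM texture features.

Voxel intensities inside the segmented tumor are first resampled to a fixed
number of gray levels (32 and 64 in the reference analysis).  Second-order
heterogeneity is captured by the normalized gray-level co-occurrence matrix
(NGLCM): for each of the 13 unique 3D directions at Chebyshev distance 1,
in-mask voxel pairs are counted in both senses (making each directional
matrix symmetric), each matrix is normalized to sum 1, and the matrices are
averaged over directions — an orientation-invariant 3D treatment.  From the
averaged matrix the Haralick-type parameters follow (uniformity, entropy,
dissimilarity, contrast, homogeneity, inverse difference moment,
correlation).

Higher-order, human-perception-like parameters come from the neighborhood
gray-tone difference matrix (NGTDM): each in-mask voxel with at least one
in-mask neighbor in its 26-neighborhood contributes the absolute difference
between its level and the mean level of those neighbors; the per-level sums
s(i) and occupancy probabilities p(i) yield coarseness, contrast, busyness,
complexity and strength (Amadasun-King definitions, with an epsilon of 1e-6
protecting the degenerate denominators).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import ImageVolume, VoiMask

#: Epsilon protecting NGTDM coarseness/strength denominators.
NGTDM_EPS = 1e-6

#: Entropy is reported in bits (log base 2); recorded here so cutoffs are
#: reproducible against either convention.
ENTROPY_LOG_BASE = 2

#: The 13 unique displacement directions at Chebyshev distance 1 in 3D
#: (one representative per +/- pair of the 26-neighborhood).
OFFSETS_13 = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

NGLCM_FEATURE_NAMES = (
    "uniformity", "entropy", "dissimilarity", "contrast",
    "homogeneity", "inverse_difference_moment", "correlation",
)
NGTDM_FEATURE_NAMES = ("coarseness", "ngtdm_contrast", "busyness", "complexity", "strength")


@dataclass
class LabelVolume:
    """Resampled gray-level labels 1..bins inside the mask, 0 outside."""

    data: np.ndarray
    bins: int
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int64)
        self.mask = np.asarray(self.mask, dtype=bool)
        inside = self.data[self.mask]
        if inside.size and (inside.min() < 1 or inside.max() > self.bins):
            raise ValueError("labels inside the mask must lie in [1, bins]")


@dataclass
class Nglcm:
    """Normalized, direction-averaged gray-level co-occurrence matrix."""

    matrix: np.ndarray
    bins: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (self.bins, self.bins):
            raise ValueError("co-occurrence matrix must be bins x bins")
        if not math.isclose(self.matrix.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("co-occurrence matrix entries must sum to 1")


@dataclass
class NglcmFeatures:
    uniformity: float
    entropy: float
    dissimilarity: float
    contrast: float
    homogeneity: float
    inverse_difference_moment: float
    correlation: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in NGLCM_FEATURE_NAMES}


@dataclass
class NgtdmFeatures:
    coarseness: float
    contrast: float
    busyness: float
    complexity: float
    strength: float

    def as_dict(self) -> dict[str, float]:
        return {
            "coarseness": self.coarseness,
            "ngtdm_contrast": self.contrast,
            "busyness": self.busyness,
            "complexity": self.complexity,
            "strength": self.strength,
        }


# ---------------------------------------------------------------------------
# Intensity resampling
# ---------------------------------------------------------------------------

def resample_intensities(
    volume: ImageVolume | np.ndarray,
    mask: VoiMask | np.ndarray,
    bins: int,
) -> LabelVolume:
    """Fixed-bin-number discretization of in-mask intensities to 1..bins.

    label = 1 + floor(bins * (I - I_min) / (I_max - I_min)), with the
    maximum intensity mapped to ``bins``.  Raises for a constant region
    (the intensity range, and hence the binning, is undefined).
    """
    data = volume.data if isinstance(volume, ImageVolume) else np.asarray(volume, dtype=float)
    m = mask.data if isinstance(mask, VoiMask) else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("mask is empty")
    vals = data[m]
    vmin, vmax = float(vals.min()), float(vals.max())
    if vmax <= vmin:
        raise ValueError("constant intensity inside the mask: resampling range undefined")
    labels = np.zeros(data.shape, dtype=np.int64)
    scaled = np.floor(bins * (data[m] - vmin) / (vmax - vmin)).astype(np.int64) + 1
    labels[m] = np.minimum(scaled, bins)
    return LabelVolume(data=labels, bins=bins, mask=m)


# ---------------------------------------------------------------------------
# NGLCM
# ---------------------------------------------------------------------------

def _directional_counts(labels: np.ndarray, mask: np.ndarray, offset, bins: int) -> np.ndarray:
    """Symmetric co-occurrence counts for one displacement direction."""
    sl_a, sl_b = [], []
    for d, n in zip(offset, labels.shape):
        if d >= 0:
            sl_a.append(slice(0, n - d))
            sl_b.append(slice(d, n))
        else:
            sl_a.append(slice(-d, n))
            sl_b.append(slice(0, n + d))
    la = labels[tuple(sl_a)]
    lb = labels[tuple(sl_b)]
    valid = mask[tuple(sl_a)] & mask[tuple(sl_b)]
    i = la[valid] - 1
    j = lb[valid] - 1
    counts = np.zeros((bins, bins))
    np.add.at(counts, (i, j), 1.0)
    np.add.at(counts, (j, i), 1.0)  # opposite sense -> symmetric
    return counts


def compute_nglcm(labels: LabelVolume, mask: VoiMask | np.ndarray | None = None) -> Nglcm:
    """Direction-averaged normalized co-occurrence matrix.

    Each of the 13 directional matrices is normalized to sum 1 before
    averaging; directions without any in-mask pair are excluded from the
    average.  Raises when no direction has a valid pair.
    """
    m = labels.mask if mask is None else (
        mask.data if isinstance(mask, VoiMask) else np.asarray(mask, dtype=bool))
    mats = []
    for offset in OFFSETS_13:
        counts = _directional_counts(labels.data, m, offset, labels.bins)
        total = counts.sum()
        if total > 0:
            mats.append(counts / total)
    if not mats:
        raise ValueError("no in-mask neighbor pairs: co-occurrence matrix undefined")
    return Nglcm(matrix=np.mean(mats, axis=0), bins=labels.bins)


def nglcm_features(m: Nglcm) -> NglcmFeatures:
    """Haralick-type parameters of a normalized co-occurrence matrix.

    uniformity = sum p^2; entropy = -sum p log2 p; contrast = sum (i-j)^2 p;
    dissimilarity = sum |i-j| p; homogeneity = sum p/(1+|i-j|);
    IDM = sum p/(1+(i-j)^2); correlation = sum (i-mu)(j-mu) p / sigma^2
    (defined as 0 when sigma = 0, e.g. a one-hot matrix).
    """
    p = m.matrix
    b = m.bins
    i = np.arange(1, b + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    diff = ii - jj
    nz = p > 0
    entropy = float(-(p[nz] * np.log2(p[nz])).sum())
    px = p.sum(axis=1)  # marginal (symmetric matrix: both marginals equal)
    mu = float((i * px).sum())
    var = float(((i - mu) ** 2 * px).sum())
    if var > 0:
        correlation = float(((ii - mu) * (jj - mu) * p).sum() / var)
    else:
        correlation = 0.0
    return NglcmFeatures(
        uniformity=float((p**2).sum()),
        entropy=entropy,
        dissimilarity=float((np.abs(diff) * p).sum()),
        contrast=float((diff**2 * p).sum()),
        homogeneity=float((p / (1 + np.abs(diff))).sum()),
        inverse_difference_moment=float((p / (1 + diff**2)).sum()),
        correlation=correlation,
    )


def nglcm_features_per_direction(labels: LabelVolume, mask=None) -> NglcmFeatures:
    """Alternative route: compute features per direction, then average them.

    The default pipeline averages the directional matrices and computes
    features once; this variant averages the per-direction feature values
    instead.  Both are orientation-invariant summaries.
    """
    m = labels.mask if mask is None else (
        mask.data if isinstance(mask, VoiMask) else np.asarray(mask, dtype=bool))
    feats = []
    for offset in OFFSETS_13:
        counts = _directional_counts(labels.data, m, offset, labels.bins)
        total = counts.sum()
        if total > 0:
            f = nglcm_features(Nglcm(matrix=counts / total, bins=labels.bins))
            feats.append([getattr(f, name) for name in NGLCM_FEATURE_NAMES])
    if not feats:
        raise ValueError("no in-mask neighbor pairs")
    mean = np.mean(feats, axis=0)
    return NglcmFeatures(**dict(zip(NGLCM_FEATURE_NAMES, map(float, mean))))


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def compute_ngtdm(
    labels: LabelVolume, mask: VoiMask | np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-level occupancy p(i), summed neighbor differences s(i), n_valid.

    A voxel is valid when it has >= 1 in-mask neighbor in its full
    26-neighborhood; it contributes |label - mean(in-mask neighbor labels)|
    to s at its own level.  p(i) = count(i) / n_valid over valid voxels.
    """
    m = labels.mask if mask is None else (
        mask.data if isinstance(mask, VoiMask) else np.asarray(mask, dtype=bool))
    if not m.any():
        raise ValueError("mask is empty")
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    lab = labels.data.astype(float) * m
    nbr_sum = ndimage.convolve(lab, kernel, mode="constant", cval=0.0)
    nbr_cnt = ndimage.convolve(m.astype(float), kernel, mode="constant", cval=0.0)
    valid = m & (nbr_cnt > 0.5)
    n_valid = int(valid.sum())
    b = labels.bins
    s = np.zeros(b)
    counts = np.zeros(b)
    if n_valid:
        lv = labels.data[valid]
        diffs = np.abs(lv - nbr_sum[valid] / nbr_cnt[valid])
        np.add.at(s, lv - 1, diffs)
        np.add.at(counts, lv - 1, 1.0)
    p = counts / n_valid if n_valid else counts
    return p, s, n_valid


def ngtdm_features(p: np.ndarray, s: np.ndarray, n_valid: int, bins: int) -> NgtdmFeatures:
    """Amadasun-King texture parameters from the NGTDM components.

    Sums run over occupied levels (p_i > 0); Ng is their number.  With a
    single occupied level, contrast and busyness are 0 by convention and
    coarseness saturates at 1/eps.
    """
    if n_valid <= 0:
        raise ValueError("n_valid must be positive")
    p = np.asarray(p, dtype=float)
    s = np.asarray(s, dtype=float)
    levels = np.arange(1, bins + 1)
    occ = p > 0
    i = levels[occ]
    pi = p[occ]
    si = s[occ]
    ng = int(occ.sum())

    coarseness = 1.0 / (NGTDM_EPS + float((pi * si).sum()))
    if ng > 1:
        dij2 = (i[:, None] - i[None, :]) ** 2
        contrast = float(
            (pi[:, None] * pi[None, :] * dij2).sum() / (ng * (ng - 1))
        ) * float(si.sum()) / n_valid
        ipi = i * pi
        busy_denom = float(np.abs(ipi[:, None] - ipi[None, :]).sum())
        busyness = float((pi * si).sum()) / busy_denom if busy_denom > 0 else 0.0
        absdij = np.abs(i[:, None] - i[None, :])
        psum = pi[:, None] + pi[None, :]
        num = pi[:, None] * si[:, None] + pi[None, :] * si[None, :]
        complexity = float((absdij / (n_valid * psum) * num).sum())
        strength = float((psum * dij2).sum()) / (NGTDM_EPS + float(si.sum()))
    else:
        contrast = 0.0
        busyness = 0.0
        complexity = 0.0
        strength = 0.0
    return NgtdmFeatures(
        coarseness=coarseness,
        contrast=contrast,
        busyness=busyness,
        complexity=complexity,
        strength=strength,
    )


# ---------------------------------------------------------------------------
# One-pass extraction at several bin counts
# ---------------------------------------------------------------------------

def texture_features_all(
    volume: ImageVolume | np.ndarray,
    mask: VoiMask | np.ndarray,
    bins: tuple[int, ...] = (32, 64),
    nglcm_average: str = "matrix",
) -> dict[str, float]:
    """All NGLCM + NGTDM parameters at each bin count, keyed ``name_<bins>``.

    ``nglcm_average``: 'matrix' (average directional matrices, then compute
    features — default) or 'features' (average per-direction feature values).
    """
    if nglcm_average not in ("matrix", "features"):
        raise ValueError("nglcm_average must be 'matrix' or 'features'")
    out: dict[str, float] = {}
    for b in bins:
        labels = resample_intensities(volume, mask, b)
        if nglcm_average == "matrix":
            gf = nglcm_features(compute_nglcm(labels))
        else:
            gf = nglcm_features_per_direction(labels)
        p, s, n_valid = compute_ngtdm(labels)
        tf = ngtdm_features(p, s, n_valid, b)
        for name, value in {**gf.as_dict(), **tf.as_dict()}.items():
            out[f"{name}_{b}"] = value
    return out
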