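"""Synthetic phantoms and cohorts with known ground truth.

Every input the analysis pipeline consumes can be generated here: PET SUV
phantoms with controllable intratumor heterogeneity, dynamic
contrast-enhanced MRI series produced by the extended Kety forward model,
two-b-value DWI signal pairs from a known ADC field, and survival cohorts
whose hazard scales with a 0-4 composite risk score.  All generators are
fully deterministic under a fixed seed, and each one round-trips through
the corresponding estimation operation at zero noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import ImageVolume, VoiMask, sphere_mask
from .mri import AifCurve, VfaAcquisition, kety_forward, KetyParams, spgr_signal

#: Margin (mm) added around the lesion radius when drawing the generous VOI,
#: emulating a manually drawn boundary that comfortably encloses the tumor.
VOI_MARGIN_MM = 6.0

TEXTURES = ("constant", "two-level-checker", "gaussian-random-field")


@dataclass
class LesionSpec:
    """Specification of a spherical lesion embedded in low-uptake background.

    ``heterogeneity_texture`` controls the intratumor SUV pattern:

    - ``constant``: every lesion voxel at ``lesion_suv_mean``;
    - ``two-level-checker``: alternating ``lesion_suv_mean +/- checker_delta``
      on the voxel parity lattice — maximal short-range heterogeneity;
    - ``gaussian-random-field``: mean plus a smoothed Gaussian field with
      marginal standard deviation ``grf_sd`` and correlation length
      ``grf_correlation_mm``.
    """

    center: tuple[float, float, float]  # voxel coordinates
    radius_mm: float
    background_suv: float = 1.0
    lesion_suv_mean: float = 8.0
    heterogeneity_texture: str = "constant"
    checker_delta: float = 2.0
    grf_sd: float = 1.0
    grf_correlation_mm: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        if self.lesion_suv_mean <= self.background_suv:
            raise ValueError("lesion_suv_mean must exceed background_suv")
        if self.heterogeneity_texture not in TEXTURES:
            raise ValueError(
                f"unknown texture {self.heterogeneity_texture!r}; expected one of {TEXTURES}"
            )


@dataclass
class PetPhantom:
    """A generated PET phantom: SUV volume, generous VOI, and the truth mask."""

    volume: ImageVolume
    voi: VoiMask
    lesion_mask: VoiMask


def generate_pet_phantom(
    spec: LesionSpec,
    shape: tuple[int, int, int] = (48, 48, 48),
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0),
) -> PetPhantom:
    """Embed a spherical lesion in a uniform background SUV volume.

    Voxels belong to the lesion when their centre lies within ``radius_mm``
    of the centre point (physical distance), which makes the lesion voxel
    count exactly enumerable.  The returned VOI is a larger sphere
    (radius + ``VOI_MARGIN_MM``) clipped to the grid, standing in for a
    manually drawn boundary that generously encloses the tumor.
    """
    spacing = tuple(float(s) for s in spacing_mm)
    # reject lesions that do not fit on the grid
    for ax, (c, s, n) in enumerate(zip(spec.center, spacing, shape)):
        lo = c - spec.radius_mm / s
        hi = c + spec.radius_mm / s
        if lo < -0.5 or hi > n - 0.5:
            raise ValueError(
                f"lesion extent [{lo:.2f}, {hi:.2f}] voxels exceeds grid of "
                f"{n} voxels along axis {ax}"
            )
    lesion = sphere_mask(shape, spacing, spec.center, spec.radius_mm)
    if not lesion.any():
        raise ValueError("lesion contains no voxel centres; increase radius or resolution")
    rng = np.random.default_rng(spec.seed)
    data = np.full(shape, spec.background_suv, dtype=float)

    if spec.heterogeneity_texture == "constant":
        data[lesion] = spec.lesion_suv_mean
    elif spec.heterogeneity_texture == "two-level-checker":
        grids = np.indices(shape).sum(axis=0)
        hi = (grids % 2 == 0) & lesion
        lo = (grids % 2 == 1) & lesion
        data[hi] = spec.lesion_suv_mean + spec.checker_delta
        data[lo] = spec.lesion_suv_mean - spec.checker_delta
    else:  # gaussian-random-field
        white = rng.standard_normal(shape)
        sigma_vox = [spec.grf_correlation_mm / s for s in spacing]
        smooth = ndimage.gaussian_filter(white, sigma=sigma_vox)
        smooth = smooth / smooth.std()  # unit marginal sd over the grid
        field = spec.lesion_suv_mean + spec.grf_sd * smooth
        data[lesion] = field[lesion]

    voi = sphere_mask(shape, spacing, spec.center, spec.radius_mm + VOI_MARGIN_MM)
    volume = ImageVolume(data=data, spacing_mm=spacing, modality="PET_SUV")
    return PetPhantom(volume=volume, voi=VoiMask(voi), lesion_mask=VoiMask(lesion))


# ---------------------------------------------------------------------------
# Population arterial input function
# ---------------------------------------------------------------------------

#: Bi-exponential population AIF parameters (Weinmann-type, standard Gd dose):
#: Cp(t') = dose * (a1 exp(-m1 t') + a2 exp(-m2 t')) after bolus arrival,
#: with amplitudes in kg/L and rates in min^-1.
AIF_A1, AIF_A2 = 3.99, 4.78      # kg/L
AIF_M1, AIF_M2 = 0.144, 0.0111   # min^-1
AIF_DOSE = 0.1                   # mmol/kg


def population_aif(times_s: Sequence[float], bolus_arrival_s: float = 13.2) -> AifCurve:
    """Analytic bi-exponential population AIF on a time grid in seconds.

    Zero before ``bolus_arrival_s`` (default = four baseline frames at the
    3.3 s dynamic frame interval), bi-exponential decay afterwards.
    """
    t = np.asarray(times_s, dtype=float)
    tp_min = np.clip((t - bolus_arrival_s) / 60.0, 0.0, None)
    # amplitudes (kg/L) x dose (mmol/kg) give mmol/L = mM directly
    decay = AIF_A1 * np.exp(-AIF_M1 * tp_min) + AIF_A2 * np.exp(-AIF_M2 * tp_min)
    cp = np.where((t - bolus_arrival_s) >= 0, AIF_DOSE * decay, 0.0)
    return AifCurve(times=t, cp=cp)


def default_dce_times(n_frames: int = 80, dt_s: float = 3.3) -> np.ndarray:
    """Uniform dynamic time grid: 80 frames at 3.3 s temporal resolution."""
    return np.arange(n_frames) * dt_s


# ---------------------------------------------------------------------------
# DCE series generation
# ---------------------------------------------------------------------------

@dataclass
class DceSeries:
    """Synthetic DCE acquisition: dynamic 4D signal + VFA baseline volumes."""

    dynamic: np.ndarray          # (..., t)
    vfa_volumes: np.ndarray      # (n_angles, ...)
    times: np.ndarray            # s
    aif: AifCurve
    acquisition: VfaAcquisition
    m0: float
    truth: dict                  # ground-truth maps


def generate_dce_series(
    ktrans_map: np.ndarray,
    ve_map: np.ndarray,
    vp_map: np.ndarray,
    aif: AifCurve,
    times: Sequence[float] | None = None,
    t10_map: np.ndarray | float = 1000.0,
    acquisition: VfaAcquisition = VfaAcquisition(),
    m0: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DceSeries:
    """Forward-simulate a DCE-MRI acquisition from extended-Kety ground truth.

    Pipeline: Kety forward model -> contrast concentration -> T1(t) via the
    relaxivity relation -> spoiled-gradient-echo signal at the dynamic flip
    angle; the multi-flip-angle baseline volumes are produced from the same
    T1_0 and m0.  Additive Gaussian noise of ``noise_sd`` signal units is
    applied to every volume (zero noise leaves the series exactly
    invertible by the estimation operations).
    """
    ktrans = np.atleast_1d(np.asarray(ktrans_map, dtype=float))
    ve = np.broadcast_to(np.asarray(ve_map, dtype=float), ktrans.shape)
    vp = np.broadcast_to(np.asarray(vp_map, dtype=float), ktrans.shape)
    if np.any((ve <= 0) | (ve > 1)) or np.any((vp < 0) | (vp >= 1)):
        raise ValueError("ve must lie in (0,1] and vp in [0,1)")
    t = default_dce_times() if times is None else np.asarray(times, dtype=float)
    if t.size > 1 and not np.allclose(np.diff(t), t[1] - t[0]):
        raise ValueError("dynamic time grid must be uniformly spaced")
    if aif.times.shape != t.shape or not np.allclose(aif.times, t):
        raise ValueError("AIF must be sampled on the dynamic time grid")
    t10 = np.broadcast_to(np.asarray(t10_map, dtype=float), ktrans.shape)
    if np.any(t10 <= 0):
        raise ValueError("t10_map must be positive everywhere")

    ct = np.empty(ktrans.shape + t.shape)
    for idx in np.ndindex(ktrans.shape):
        p = KetyParams(ktrans=float(ktrans[idx]), ve=float(ve[idx]), vp=float(vp[idx]))
        ct[idx] = kety_forward(p, aif)

    # concentration -> T1(t) (ms): 1/T1_s = 1/T10_s + r1 * C
    r1 = acquisition.r1
    t1_t = 1.0 / (1.0 / t10[..., None] + r1 * ct / 1000.0)
    dyn = spgr_signal(m0, t1_t, acquisition.tr_ms, acquisition.dynamic_flip_deg)
    vfa = np.stack(
        [
            spgr_signal(m0, t10, acquisition.tr_ms, alpha)
            for alpha in acquisition.flip_angles_deg
        ]
    )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        dyn = dyn + rng.normal(0.0, noise_sd, size=dyn.shape)
        vfa = vfa + rng.normal(0.0, noise_sd, size=vfa.shape)
    truth = {"ktrans": ktrans, "ve": np.array(ve), "vp": np.array(vp),
             "kep": ktrans / ve, "t10": np.array(t10), "ct": ct}
    return DceSeries(
        dynamic=dyn, vfa_volumes=vfa, times=t, aif=aif,
        acquisition=acquisition, m0=m0, truth=truth,
    )


# ---------------------------------------------------------------------------
# DWI pair generation
# ---------------------------------------------------------------------------

def generate_dwi_pair(
    adc_map: np.ndarray,
    s0: float = 1000.0,
    b: float = 800.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-b-value DWI signals: Sb = s0 exp(-b ADC) (+ Gaussian noise).

    ``adc_map`` is in the conventional 1e-3 mm^2/s units; ``b`` in s/mm^2.
    Returns (b0 volume, b volume).
    """
    if b <= 0:
        raise ValueError("b must be positive")
    adc = np.asarray(adc_map, dtype=float)
    if np.any(adc < 0):
        raise ValueError("adc_map must be nonnegative")
    s0_vol = np.full(adc.shape, float(s0))
    sb_vol = s0 * np.exp(-b * adc * 1e-3)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        s0_vol = s0_vol + rng.normal(0.0, noise_sd, size=adc.shape)
        sb_vol = sb_vol + rng.normal(0.0, noise_sd, size=adc.shape)
    return s0_vol, sb_vol


# ---------------------------------------------------------------------------
# Survival cohorts
# ---------------------------------------------------------------------------

#: Default score distribution over 0..4, shaped like the occupied strata of
#: an advanced-disease cohort in which every patient carries >= 1 risk factor.
DEFAULT_SCORE_PROBS = (0.0, 0.09, 0.42, 0.38, 0.11)

#: Cutoffs used to place continuous feature values on the correct side of
#: the risk rules when building synthetic patients.
OS_CUTOFFS = {"ktrans": 0.5512, "kep": 0.8872, "uniformity": 0.00381}


@dataclass
class CohortSpec:
    """Specification of a synthetic survival cohort.

    Event times are exponential with per-patient hazard
    ``baseline_hazard * hazard_ratio_per_point ** score`` (1/month) and are
    administratively censored at ``censor_time`` months.
    """

    n: int
    score_probs: tuple[float, ...] = DEFAULT_SCORE_PROBS
    baseline_hazard: float = 0.004
    hazard_ratio_per_point: float = 2.0
    censor_time: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        p = np.asarray(self.score_probs, dtype=float)
        if p.size != 5 or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("score_probs must be 5 nonnegative values summing to 1")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.hazard_ratio_per_point <= 0:
            raise ValueError("hazard_ratio_per_point must be positive")
        if self.censor_time < 0:
            raise ValueError("censor_time must be nonnegative")


#: Risk factors underlying the overall-survival score, in assignment order.
_OS_FACTORS = ("smoking", "ktrans_low", "kep_low", "uniformity_low")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a synthetic cohort with hazard tied to the composite risk score.

    Each patient receives a score from ``score_probs``; a random subset of
    the four risk factors of that size is switched on, and continuous
    feature values (ktrans, kep, uniformity) are drawn uniformly on the
    matching side of their cutoffs.  OS and RFS event times are independent
    exponentials under the same score-driven hazard, censored at
    ``censor_time``.
    """
    rng = np.random.default_rng(spec.seed)
    scores = rng.choice(5, size=spec.n, p=np.asarray(spec.score_probs, dtype=float))
    rows = []
    for i, score in enumerate(scores):
        on = np.zeros(4, dtype=bool)
        on[rng.choice(4, size=score, replace=False)] = True
        flags = dict(zip(_OS_FACTORS, on))
        ktrans = (rng.uniform(0.05, OS_CUTOFFS["ktrans"]) if flags["ktrans_low"]
                  else rng.uniform(OS_CUTOFFS["ktrans"] + 1e-6, 2.0))
        kep = (rng.uniform(0.1, OS_CUTOFFS["kep"]) if flags["kep_low"]
               else rng.uniform(OS_CUTOFFS["kep"] + 1e-6, 3.0))
        uniformity = (rng.uniform(0.001, OS_CUTOFFS["uniformity"]) if flags["uniformity_low"]
                      else rng.uniform(OS_CUTOFFS["uniformity"] + 1e-7, 0.02))
        hazard = spec.baseline_hazard * spec.hazard_ratio_per_point ** score
        t_os = rng.exponential(1.0 / hazard)
        t_rfs = rng.exponential(1.0 / hazard)
        rows.append({
            "id": f"P{i:04d}",
            "score": int(score),
            "smoking": bool(flags["smoking"]),
            "alcohol": bool(rng.random() < 0.65),
            "subsite": "hypopharynx" if rng.random() < 0.5 else "oropharynx",
            "ktrans": ktrans,
            "kep": kep,
            "uniformity": uniformity,
            "suv": float(rng.uniform(5.0, 25.0)),
            "os_months": min(t_os, spec.censor_time),
            "os_event": int(t_os <= spec.censor_time),
            "rfs_months": min(t_rfs, spec.censor_time),
            "rfs_event": int(t_rfs <= spec.censor_time),
        })
    return pd.DataFrame(rows)
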