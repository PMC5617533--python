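"""DCE-MRI pharmacokinetics and DWI diffusion mapping.

Dynamic contrast-enhanced MRI is modelled with the extended Kety (extended
Tofts) model,

    C_t(t) = v_p * C_p(t) + Ktrans * int_0^t C_p(tau) exp(-k_ep (t - tau)) dtau,

where ``Ktrans`` (min^-1) is the plasma-to-interstitium transfer constant,
``v_e`` and ``v_p`` the fractional interstitial and plasma volumes, and
``k_ep = Ktrans / v_e`` the efflux rate constant.  Signal is related to
contrast concentration through the spoiled-gradient-echo (SPGR) equation and
the longitudinal relaxivity r1:  1/T1(t) = 1/T1_0 + r1 * C(t).  Baseline T1_0
is estimated from multi-flip-angle SPGR acquisitions by the linearised
DESPOT1 regression.  DWI yields the apparent diffusion coefficient from a
two-point signal decay, ADC = ln(S0/Sb)/b.

Time grids are in seconds throughout; rate constants are reported in min^-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .core import VoiMask

SEC_PER_MIN = 60.0

#: Fit bounds: ktrans in [0, 5] min^-1, ve in (1e-3, 1], vp in [0, 0.5].
KETY_BOUNDS = ((0.0, 1e-3, 0.0), (5.0, 1.0, 0.5))


@dataclass
class AifCurve:
    """Arterial input function: plasma contrast concentration over time.

    times : seconds, strictly increasing; cp : mM, zero before bolus arrival.
    """

    times: np.ndarray
    cp: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cp = np.asarray(self.cp, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.cp.shape:
            raise ValueError("times and cp must be 1D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.cp < 0):
            raise ValueError("cp must be nonnegative")


@dataclass
class KetyParams:
    """Extended-Kety parameters; ``kep`` is derived as ``ktrans / ve``."""

    ktrans: float  # min^-1
    ve: float      # dimensionless in (0, 1]
    vp: float      # dimensionless in [0, 1)

    def __post_init__(self) -> None:
        if not (0 < self.ve <= 1):
            raise ValueError(f"ve must lie in (0, 1], got {self.ve}")
        if not (0 <= self.vp < 1):
            raise ValueError(f"vp must lie in [0, 1), got {self.vp}")
        if self.ktrans < 0:
            raise ValueError(f"ktrans must be nonnegative, got {self.ktrans}")

    @property
    def kep(self) -> float:
        """Efflux rate constant Ktrans / ve (min^-1)."""
        return self.ktrans / self.ve


@dataclass
class VfaAcquisition:
    """Spoiled-gradient-echo acquisition parameters for VFA T1 mapping."""

    tr_ms: float = 3.5
    flip_angles_deg: tuple[float, ...] = (4.0, 8.0, 15.0, 25.0)
    dynamic_flip_deg: float = 15.0
    r1: float = 3.6  # relaxivity, s^-1 mM^-1 (Gd-DTPA at 3 T)
    n_baseline: int = 4  # pre-bolus dynamic frames

    def __post_init__(self) -> None:
        if self.tr_ms <= 0:
            raise ValueError("tr_ms must be positive")


# ---------------------------------------------------------------------------
# SPGR signal model and VFA T1 mapping
# ---------------------------------------------------------------------------

def spgr_signal(m0, t1_ms, tr_ms: float, alpha_deg) -> np.ndarray | float:
    """Spoiled gradient-echo signal S = m0 sin(a) (1 - E) / (1 - E cos(a)).

    ``E = exp(-TR/T1)``.  Accepts scalars or broadcastable arrays.
    """
    t1_ms = np.asarray(t1_ms, dtype=float)
    if np.any(t1_ms <= 0):
        raise ValueError("t1_ms must be positive")
    if tr_ms <= 0:
        raise ValueError("tr_ms must be positive")
    a = np.deg2rad(alpha_deg)
    e = np.exp(-tr_ms / t1_ms)
    out = np.asarray(m0, dtype=float) * np.sin(a) * (1 - e) / (1 - e * np.cos(a))
    return out if out.ndim else float(out)


def fit_t10_vfa(signals, acquisition: VfaAcquisition) -> tuple[float, float]:
    """Estimate baseline T1 and m0 from multi-flip-angle SPGR signals.

    Uses the linearised DESPOT1 form: regressing y = S/sin(a) against
    x = S/tan(a) gives slope E = exp(-TR/T1) and intercept m0 (1 - E).

    Returns (t10_ms, m0).  Raises if fewer than two angles are supplied or
    the fitted slope is outside (0, 1) (non-physical T1).
    """
    s = np.asarray(signals, dtype=float)
    angles = np.asarray(acquisition.flip_angles_deg, dtype=float)
    if s.shape != angles.shape:
        raise ValueError("need one signal per flip angle")
    if s.size < 2:
        raise ValueError("VFA T1 fitting requires at least two flip angles")
    if np.any(s <= 0):
        raise ValueError("signals must be positive")
    a = np.deg2rad(angles)
    y = s / np.sin(a)
    x = s / np.tan(a)
    slope, intercept = np.polyfit(x, y, 1)
    if not (0 < slope < 1):
        raise ValueError(f"non-physical VFA slope {slope:.4g}; T1 undefined")
    t10_ms = -acquisition.tr_ms / np.log(slope)
    m0 = intercept / (1 - slope)
    return float(t10_ms), float(m0)


def fit_t10_vfa_map(vfa_volumes, acquisition: VfaAcquisition) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised DESPOT1 over a stack of flip-angle volumes.

    ``vfa_volumes``: array (n_angles, ...).  Returns (t10_ms map, m0 map).
    """
    s = np.asarray(vfa_volumes, dtype=float)
    a = np.deg2rad(np.asarray(acquisition.flip_angles_deg, dtype=float))
    a = a.reshape((-1,) + (1,) * (s.ndim - 1))
    y = s / np.sin(a)
    x = s / np.tan(a)
    xm = x.mean(axis=0)
    ym = y.mean(axis=0)
    slope = ((x - xm) * (y - ym)).sum(axis=0) / ((x - xm) ** 2).sum(axis=0)
    slope = np.clip(slope, 1e-12, 1 - 1e-12)
    intercept = ym - slope * xm
    t10 = -acquisition.tr_ms / np.log(slope)
    m0 = intercept / (1 - slope)
    return t10, m0


# ---------------------------------------------------------------------------
# Signal <-> concentration
# ---------------------------------------------------------------------------

def signal_to_concentration(
    dyn_signal: np.ndarray,
    t10_ms,
    m0=None,
    acquisition: VfaAcquisition = VfaAcquisition(),
) -> tuple[np.ndarray, np.ndarray]:
    """Convert a dynamic SPGR signal time course to contrast concentration.

    Inverts the SPGR equation for T1(t) at the dynamic flip angle, then
    applies 1/T1(t) = 1/T1_0 + r1 C(t).  By default the equilibrium
    magnetisation is re-derived from the mean of the pre-bolus baseline
    frames (first ``acquisition.n_baseline``) together with T1_0, which
    pins C = 0 on the baseline up to noise; pass ``m0`` explicitly to use
    the VFA-fitted value instead.

    Accepts a 1D time course or an array with time on the last axis.
    Returns (concentration mM, flagged boolean array) where flagged samples
    implied a non-physical T1 and are set to NaN.
    """
    s = np.asarray(dyn_signal, dtype=float)
    a = np.deg2rad(acquisition.dynamic_flip_deg)
    t10_arr = np.asarray(t10_ms, dtype=float)
    if np.any(t10_arr <= 0):
        raise ValueError("t10_ms must be positive")
    if m0 is None:
        # baseline normalisation: S_base = m0 sin(a)(1-E10)/(1-E10 cos a)
        n_base = acquisition.n_baseline
        if s.shape[-1] <= n_base:
            raise ValueError("dynamic series shorter than the pre-bolus baseline")
        s_base = s[..., :n_base].mean(axis=-1)
        e10 = np.exp(-acquisition.tr_ms / t10_arr)
        m0 = s_base * (1 - e10 * np.cos(a)) / (np.sin(a) * (1 - e10))
    m0 = np.asarray(m0, dtype=float)[..., np.newaxis] if np.ndim(m0) else float(m0)
    denom = np.sin(a) * m0 - np.cos(a) * s
    e = np.divide(np.sin(a) * m0 - s, denom, out=np.full_like(s, np.nan), where=denom != 0)
    flagged = ~((e > 0) & (e < 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        t1 = -acquisition.tr_ms / np.log(np.where(flagged, 0.5, e))
    t10 = t10_arr[..., np.newaxis] if t10_arr.ndim else t10_arr
    # relaxation rates in s^-1: T1 given in ms
    conc = (1000.0 / t1 - 1000.0 / t10) / acquisition.r1
    conc = np.where(flagged, np.nan, conc)
    return conc, flagged


# ---------------------------------------------------------------------------
# Extended Kety model
# ---------------------------------------------------------------------------

def _exp_convolution(times: np.ndarray, cp: np.ndarray, kep_per_s: float) -> np.ndarray:
    """Exact integral of a piecewise-linear C_p against exp(-kep (t - tau)).

    On each interval the AIF is linear, C_p(tau) = c0 + r (tau - t_k); the
    segment integral has the closed form used below.  The running integral
    satisfies I(t_{k+1}) = I(t_k) e^{-kep dt} + segment, which is evaluated
    sequentially (O(n) per curve).
    """
    n = times.size
    out = np.zeros(n)
    if kep_per_s < 1e-12:
        # kep -> 0: plain cumulative trapezoid
        dt = np.diff(times)
        out[1:] = np.cumsum(0.5 * dt * (cp[1:] + cp[:-1]))
        return out
    acc = 0.0
    for k in range(n - 1):
        dt = times[k + 1] - times[k]
        c0, c1 = cp[k], cp[k + 1]
        r = (c1 - c0) / dt
        e = np.exp(-kep_per_s * dt)
        # int_0^dt (c0 + r u) e^{-kep (dt - u)} du
        seg = (c1 - c0 * e) / kep_per_s - r * (1 - e) / kep_per_s**2
        acc = acc * e + seg
        out[k + 1] = acc
    return out


def kety_forward(params: KetyParams, aif: AifCurve) -> np.ndarray:
    """Tissue concentration C_t(t) (mM) from the extended Kety model.

    ``aif.times`` in seconds; ``params.ktrans``/``kep`` in min^-1 (converted
    internally).  The convolution integrates the piecewise-linear AIF
    against the exponential kernel exactly.
    """
    ktrans_s = params.ktrans / SEC_PER_MIN
    kep_s = params.kep / SEC_PER_MIN
    conv = _exp_convolution(aif.times, aif.cp, kep_s)
    return params.vp * aif.cp + ktrans_s * conv


@dataclass
class KetyFit:
    """Result of an extended-Kety fit for one voxel/ROI."""

    params: KetyParams
    residual_norm: float
    converged: bool
    flagged: bool = False
    message: str = ""

    @property
    def ktrans(self) -> float:
        return self.params.ktrans

    @property
    def ve(self) -> float:
        return self.params.ve

    @property
    def vp(self) -> float:
        return self.params.vp

    @property
    def kep(self) -> float:
        return self.params.kep


_DEFAULT_STARTS = (
    (0.1, 0.2, 0.02),
    (0.5, 0.5, 0.05),
    (1.5, 0.3, 0.01),
)


def fit_extended_kety(
    ct: np.ndarray,
    aif: AifCurve,
    init: tuple[float, float, float] | None = None,
    bounds=KETY_BOUNDS,
) -> KetyFit:
    """Bounded nonlinear least-squares fit of (ktrans, ve, vp) to C_t(t).

    ``kep`` is derived as ktrans/ve.  Non-convergence (or a residual norm
    large relative to the data) yields a flagged result with diagnostics
    rather than an exception.  Flagged voxels get a 3-point multi-start and
    the best restart is kept.
    """
    ct = np.asarray(ct, dtype=float)
    if ct.size < 10:
        raise ValueError("need at least 10 time points to fit the extended Kety model")
    if ct.shape != aif.times.shape:
        raise ValueError("ct must be aligned with the AIF time grid")
    finite = np.isfinite(ct)
    times, cp = aif.times[finite], aif.cp[finite]
    y = ct[finite]
    if y.size < 10:
        raise ValueError("fewer than 10 finite samples in ct")
    aif_f = AifCurve(times=times, cp=cp)

    def residuals(theta):
        p = KetyParams(ktrans=theta[0], ve=theta[1], vp=theta[2])
        return kety_forward(p, aif_f) - y

    def run(x0):
        return least_squares(residuals, x0=np.asarray(x0), bounds=bounds, method="trf")

    sol = run(init if init is not None else _DEFAULT_STARTS[0])
    scale = max(np.linalg.norm(y), 1e-12)
    if not sol.success or np.linalg.norm(sol.fun) > 0.05 * scale:
        for x0 in _DEFAULT_STARTS:
            trial = run(x0)
            if np.linalg.norm(trial.fun) < np.linalg.norm(sol.fun):
                sol = trial
    resid = float(np.linalg.norm(sol.fun))
    params = KetyParams(ktrans=float(sol.x[0]), ve=float(sol.x[1]), vp=float(sol.x[2]))
    flagged = (not sol.success) or resid > 0.25 * scale
    return KetyFit(
        params=params,
        residual_norm=resid,
        converged=bool(sol.success),
        flagged=flagged,
        message=str(sol.message),
    )


def fit_kety_map(
    ct_map: np.ndarray,
    aif: AifCurve,
    mask: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Voxel-wise extended-Kety fit over a concentration map (..., t).

    Returns maps of ``ktrans``, ``ve``, ``vp``, ``kep`` (NaN outside mask)
    plus ``residual`` and a boolean ``flagged`` map.
    """
    ct_map = np.asarray(ct_map, dtype=float)
    spatial = ct_map.shape[:-1]
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    out = {k: np.full(spatial, np.nan) for k in ("ktrans", "ve", "vp", "kep", "residual")}
    out["flagged"] = np.zeros(spatial, dtype=bool)
    for idx in zip(*np.nonzero(mask)):
        fit = fit_extended_kety(ct_map[idx], aif)
        out["ktrans"][idx] = fit.ktrans
        out["ve"][idx] = fit.ve
        out["vp"][idx] = fit.vp
        out["kep"][idx] = fit.kep
        out["residual"][idx] = fit.residual_norm
        out["flagged"][idx] = fit.flagged
    return out


# ---------------------------------------------------------------------------
# DWI: apparent diffusion coefficient
# ---------------------------------------------------------------------------

def compute_adc(s0_vol: np.ndarray, sb_vol: np.ndarray, b: float = 800.0) -> np.ndarray:
    """ADC map in units of 1e-3 mm^2/s from a two-b-value acquisition.

    ADC = ln(S0/Sb) / b, reported x 1000 to match the conventional scale.
    Voxels with Sb > S0 yield negative ADC and are reported as-is (the
    caller may exclude them via :func:`roi_summarize`); non-positive
    signals are NaN.
    """
    if b <= 0:
        raise ValueError("b must be positive")
    s0 = np.asarray(s0_vol, dtype=float)
    sb = np.asarray(sb_vol, dtype=float)
    valid = (s0 > 0) & (sb > 0)
    adc = np.full(s0.shape, np.nan)
    adc[valid] = np.log(s0[valid] / sb[valid]) / b * 1e3
    n_neg = int(np.sum(adc[valid] < 0))
    if n_neg:
        warnings.warn(f"{n_neg} voxels with Sb > S0 produced negative ADC", stacklevel=2)
    return adc


def roi_summarize(
    value_map: np.ndarray,
    mask: VoiMask | np.ndarray,
    statistic: str = "mean",
    flagged: np.ndarray | None = None,
) -> float:
    """Summarise a parameter map over a region of interest.

    Non-finite voxels and voxels marked in ``flagged`` are excluded.
    ``statistic``: 'mean' (default) or 'median'.
    """
    m = mask.data if isinstance(mask, VoiMask) else np.asarray(mask, dtype=bool)
    vals = np.asarray(value_map, dtype=float)[m]
    keep = np.isfinite(vals)
    if flagged is not None:
        keep &= ~np.asarray(flagged, dtype=bool)[m]
    vals = vals[keep]
    if vals.size == 0:
        raise ValueError("no valid voxels in ROI")
    if statistic == "mean":
        return float(vals.mean())
    if statistic == "median":
        return float(np.median(vals))
    raise ValueError(f"unknown statistic {statistic!r}")
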