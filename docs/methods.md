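# Methods

## Scope and data model

The package analyzes one primary tumor per patient on three imaging axes —
¹⁸F-FDG PET SUV volumes, dynamic contrast-enhanced MRI, and two-b-value
diffusion MRI — and links the resulting parameters to overall survival (OS)
and recurrence-free survival (RFS) through a composite 0–4 risk score.
Volumes are 3D scalar arrays with physical voxel spacing; masks share the
grid voxel-for-voxel. All geometric membership (lesion spheres, background
spheres) is decided by voxel-centre distance in millimetres, which makes
every voxel count exactly enumerable and keeps volume oracles trivial.

## PET segmentation and conventional parameters

Two segmentation modes operate inside a generously drawn VOI:

- **fixed**: SUV strictly greater than 2.5 (ties at the threshold are
  excluded; the strict inequality is recorded in output metadata so tie
  handling is reproducible);
- **adaptive**: T = background + f·(SUVmax − background) with f = 0.5 by
  default, where the background is the mean SUV of a 10-mm-diameter sphere
  placed in a lesion-free region. The precise adaptive rule in the
  literature varies; this background-referenced fraction-of-contrast form
  is a declared, configurable choice recorded in output metadata.

An optional largest-26-connected-component filter guards against disjoint
physiologic-uptake specks inside the VOI. It is **off by default** so that
the segmentation postcondition is exactly `voi ∧ (SUV > T)`; enable it when
VOIs are drawn loosely around physiologic uptake.

MTV is the voxel count times voxel volume (mL); TLG = SUVmean × MTV. On a
1-mm spherical phantom the voxel-centre MTV is within 5% of (4/3)πr³.

## Heterogeneity: NGLCM and NGTDM

Intensities inside the segmented tumor are discretized to a fixed **number**
of bins (32 and 64), label = 1 + ⌊B·(I−I_min)/(I_max−I_min)⌋ with the
maximum clamped to B. A constant region raises an error (the range is
undefined). Fixed-bin-number discretization is sensitive to the per-lesion
intensity range; this is a known repeatability limitation of the approach
and is intentional here.

**NGLCM.** The 13 unique displacement directions at Chebyshev distance 1
are scanned; for each, in-mask pairs are counted in both senses (the matrix
is symmetric by construction), the directional matrix is normalized to sum
1, and the matrices are averaged over the directions that contain at least
one pair. Features use the standard Haralick forms; entropy is log base 2
(declared, since published cutoffs are consistent with either base);
correlation is defined as 0 when the marginal variance is 0 (one-hot
matrix). An alternative route that averages per-direction feature values
instead of matrices is provided (`nglcm_average="features"`); matrix
averaging is the default.

**NGTDM.** The neighborhood is the full 26-neighborhood restricted to
in-mask voxels; voxels with no in-mask neighbor are excluded from n_valid.
Features follow the Amadasun–King definitions with sums over occupied
levels, ε = 1e−6 in the coarseness and strength denominators, and
contrast = busyness = 0 by convention when a single level is occupied
(coarseness then saturates at 1/ε = 1e6).

Both routes are verified exactly against independent brute-force
enumerations on hundreds of random small phantoms.

## DCE-MRI pharmacokinetics

Forward chain (also used by the generator): extended Kety model →
concentration; 1/T1(t) = 1/T1₀ + r1·C(t); spoiled-gradient-echo signal
S = m0·sinα·(1−E)/(1−E·cosα), E = exp(−TR/T1). Defaults mirror a 3-T
protocol: TR 3.5 ms, dynamic flip angle 15°, VFA angles 4/8/15/25°, 80
frames at 3.3 s, four pre-bolus baseline frames. The relaxivity default is
r1 = 3.6 s⁻¹mM⁻¹ (Gd-DTPA at 3 T), configurable. TE-dependent T2* decay is
ignored (TE ≈ 1.1 ms is negligible at these concentrations).

Estimation inverts the chain:

1. **T1₀/m0** by linearized DESPOT1 regression of S/sinα on S/tanα; a slope
   outside (0,1) is rejected as non-physical.
2. **Concentration** by inverting the SPGR equation for T1(t). By default
   the equilibrium magnetisation is re-derived from the mean of the four
   pre-bolus frames together with T1₀, which pins C = 0 on the baseline;
   samples implying non-physical T1 are flagged (NaN) rather than fatal.
3. **Extended Kety fit** by bounded trust-region least squares over
   (K^trans, v_e, v_p) with bounds [0,5] min⁻¹, (1e−3,1], [0,0.5];
   k_ep = K^trans/v_e is derived, never fitted separately. Poor fits
   (residual > 25% of the signal norm or non-convergence) are flagged with
   diagnostics and retried from 3 starting points; flagged voxels are
   excluded from ROI summaries. The ROI summary is the mean of voxel-wise
   fits (median available).

The convolution integrates the piecewise-linear AIF against the exponential
kernel in closed form per segment (O(n) recursion), so zero-noise data are
invertible essentially to machine precision; against the step-AIF analytic
solution the maximum error on the 80-frame grid is below 1e−8 mM.

Time grids are in seconds end-to-end; rate constants are reported in min⁻¹
with the conversion centralized in the model functions.

**AIF.** Blind-source-separation AIF extraction is out of scope; the
package uses a supplied AIF or its analytic bi-exponential population curve
(Weinmann-type: dose 0.1 mmol/kg, amplitudes 3.99/4.78 kg/L, rates
0.144/0.0111 min⁻¹, bolus arrival after the baseline frames). It is
reproducible and closed-form; it does not model the first-pass peak of
measured AIFs, which mainly affects v_p accuracy at coarse temporal
resolution.

## DWI

ADC = ln(S₀/S_b)/b, reported ×10⁻³ mm²/s. Negative ADC (S_b > S₀, possible
under noise) is returned but flagged with a warning; ROI summaries exclude
non-finite and flagged voxels. Only the mono-exponential two-point model is
implemented (no IVIM).

## Survival analysis and the composite score

Kaplan–Meier estimation, the k-sample log-rank test, and Cox proportional
hazards (Efron tie handling, appropriate for month-resolution ties) are
computed via `lifelines` behind the module surface; the test suite verifies
them against brute-force risk-table and partial-likelihood computations on
exhaustive small fixtures.

**Cutoff selection** scans the midpoints between consecutive distinct order
statistics, keeps splits leaving both groups ≥ 10% of the cohort
(configurable; 0 disables), and returns the cutoff maximizing the log-rank
chi-square, breaking ties toward the smaller value. The risky side is the
group with the smaller restricted mean survival. No multiplicity correction
is applied — the selected p-value is optimistic, and every report carries
this caveat explicitly.

**Risk definitions.** The OS definition counts smoking, K^trans ≤ 0.5512,
k_ep ≤ 0.8872 and NGLCM uniformity ≤ 0.00381 (32-bin uniformity is the
default mapping for the cutoff); the RFS definition counts hypopharyngeal
subsite, alcohol, K^trans ≤ 0.5512 and k_ep ≤ 0.8872. "≤" rules are
boundary-inclusive and ">" rules boundary-exclusive, matching the printed
inequalities. A two-factor comparison system (k_ep ≤ 0.887, SUV > 14.22)
is provided for side-by-side stratification reports. Collinear
heterogeneity parameters should be entered into multivariate models one at
a time; the package exposes the single-variable building blocks rather than
automating that model search.

Strata are compared with per-stratum KM curves, an overall log-rank test,
and Cox hazard ratios against the highest occupied score as reference; a
stratum pattern that makes the Cox model unidentifiable (e.g. an
event-free stratum) degrades to a warning with the HR table omitted.

## Synthetic data: what it emulates, and what it does not

- **PET phantoms**: spherical lesions (constant, two-level checkerboard, or
  smoothed Gaussian random field normalized to a target marginal SD) in a
  uniform background, with a generous VOI. No scanner physics: no OSEM
  reconstruction, attenuation, partial-volume blur or motion. Passing tests
  demonstrate correctness of the feature mathematics, not robustness to
  reconstruction artifacts.
- **DCE/DWI**: signals from the exact forward models with additive Gaussian
  noise on magnitude signals (Rician noise out of scope), so recovery tests
  measure estimator correctness and noise sensitivity, not sequence
  imperfections (B1 inhomogeneity, inflow, water exchange).
- **Cohorts**: score ~ categorical(score_probs); OS and RFS times are
  independent exponentials with hazard baseline·ratio^score, censored
  administratively. Defaults: score distribution (0, .09, .42, .38, .11)
  shaped like the occupied strata of an advanced-disease cohort in which
  every patient carries at least one factor; baseline hazard 0.004/month
  and ratio 2 per point, chosen so mid-stratum 3-year survival lands in the
  range reported for such cohorts; censoring at 60 months. Binary risk
  flags and continuous feature values are drawn consistently with the
  score, so supplied-cutoff scoring reproduces the generating score
  exactly. Real cohorts have correlated factors and non-exponential
  hazards; the generator does not emulate that.

Every generator is bit-reproducible under a fixed seed.

## Problem sizes used in validation

Texture oracle equivalence uses 200 random phantoms up to 6×6×6 voxels
(exact agreement required). The DCE round trip fits a 10×10×10 voxel map of
80-frame curves (recovery within 1% per voxel; observed worst-case ≈ 1e−4).
Cox recovery uses n = 10 000 with true HR 2 (within 3 SE). The end-to-end
power study runs 50 seeds of n = 400 cohorts at hazard ratio 2 per point —
a size at which monotone 3-year stratum ordering across four occupied
strata is expected in well over 90% of replicates; at n ≈ 124 the smallest
strata (≈ 11 patients) make occasional adjacent-stratum inversions a
sampling-noise phenomenon rather than a method failure.

## Known limitations

- The adaptive PET threshold is one member of a family of published rules;
  cross-study comparability requires matching the exact rule.
- Fixed-bin-number discretization ties texture values to the per-lesion
  SUV range; fixed-bin-width alternatives change feature scales.
- The population AIF lacks a first-pass peak; v_p estimates depend on it.
- Maximally selected cutoffs are optimistic without validation cohorts or
  resampling; the package reports the caveat but implements no correction.
- Single-lesion analysis only; no PET/MRI coregistration, no nodal VOIs,
  no competing risks or time-varying covariates.
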