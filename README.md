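# ohscc — multiparametric PET/MRI prognostics for pharyngeal cancer

`ohscc` implements a multiparametric imaging analysis for patients with
advanced oropharyngeal or hypopharyngeal squamous cell carcinoma (OHSCC)
treated with chemoradiotherapy. It combines three imaging axes with clinical
risk factors into a composite prognostic score:

- **¹⁸F-FDG PET**: metabolic tumor segmentation inside a manually drawn VOI
  (fixed SUV > 2.5 threshold, or an adaptive background-referenced
  threshold), conventional parameters (SUVmax, SUVmean, MTV, TLG), and
  intratumor *heterogeneity* parameters from the normalized gray-level
  co-occurrence matrix (NGLCM: uniformity, entropy, dissimilarity, contrast,
  homogeneity, inverse difference moment, correlation) and the neighborhood
  gray-tone difference matrix (NGTDM: coarseness, contrast, busyness,
  complexity, strength), at 32 and 64 resampled gray levels.
- **DCE-MRI**: the extended Kety (extended Tofts) model
  C_t(t) = v_p·C_p(t) + K^trans ∫₀ᵗ C_p(τ)·e^(−k_ep(t−τ)) dτ, fitted
  voxel-wise after variable-flip-angle T1₀ mapping (DESPOT1) and
  SPGR signal → concentration conversion; reports K^trans, v_e, v_p and
  k_ep = K^trans/v_e.
- **DWI**: apparent diffusion coefficient ADC = ln(S₀/S_b)/b from a
  two-b-value acquisition (b = 0 and 800 s/mm²).

Continuous parameters are dichotomized at the cutoff maximizing the log-rank
statistic over the cohort; factors that remain independent in multivariate
Cox models define a 0–4 composite score (1 point per factor present), whose
strata are compared by Kaplan–Meier curves, an overall log-rank test, and
per-stratum hazard ratios against the worst stratum.

Because clinical image archives of this kind are not publicly deposited, the
package ships a first-class synthetic-data module: PET phantoms with
controllable heterogeneity, DCE series generated by the same forward model
the fitter inverts, DWI pairs from a known ADC field, and survival cohorts
whose hazard scales as `hazard_ratio_per_point^score` — every estimator can
be validated against known ground truth.

## Worked example

```python
import numpy as np
from ohscc import (LesionSpec, generate_pet_phantom, segment_fixed_threshold,
                   conventional_features, texture_features_all, assign_score,
                   OS_RISK_DEFINITION)

spec = LesionSpec(center=(24, 24, 24), radius_mm=14.0,
                  heterogeneity_texture="gaussian-random-field", grf_sd=1.5, seed=7)
ph = generate_pet_phantom(spec)                      # 2 mm isotropic grid
tumor = segment_fixed_threshold(ph.volume, ph.voi)   # SUV > 2.5
conv = conventional_features(ph.volume, tumor)
tex = texture_features_all(ph.volume, tumor, bins=(32, 64))
print(f"SUVmax {conv.suv_max:.2f}  SUVmean {conv.suv_mean:.2f}  "
      f"MTV {conv.mtv_ml:.2f} mL  TLG {conv.tlg:.2f}")
print(f"uniformity_32 {tex['uniformity_32']:.5f}  entropy_32 {tex['entropy_32']:.3f}")

patient = {"smoking": True, "ktrans": 1.056, "kep": 1.1356,
           "uniformity": tex["uniformity_32"]}
print("OS score:", assign_score(patient, OS_RISK_DEFINITION))
```

prints

```
SUVmax 11.60  SUVmean 8.59  MTV 11.35 mL  TLG 97.52
uniformity_32 0.00326  entropy_32 8.524
OS score: 2
```

The phantom's heterogeneous lesion segments to an 11.35 mL metabolic volume;
its low uniformity (0.00326 ≤ 0.00381) marks heterogeneous glucose
metabolism, so together with smoking the patient carries 2 of the 4
overall-survival risk factors (K^trans and k_ep are above their risk
cutoffs of 0.5512 and 0.8872 min⁻¹).

A fully synthetic end-to-end study (cohort generation → scoring →
stratified survival report) runs from the shell:

```
ohscc demo --seed 7 --out demo/
```

which writes `demo/report.json`, the per-stratum Kaplan–Meier step
functions as CSV, and the scored feature table. Other subcommands
(`ohscc synth`, `petfeat`, `texture`, `adc`, `dce-fit`, `survival`,
`run`) expose each stage on NIfTI/CSV inputs; see `ohscc --help`.

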