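# promai

Automated malignancy analysis of multiparametric prostate MRI (mpMRI),
evaluated against biopsy-core pathology.

Prostate cancer is increasingly diagnosed from mpMRI — anatomical
T2-weighted (T2W) imaging combined with diffusion-weighted imaging (DWI)
and dynamic contrast-enhanced (DCE) time series — followed by MRI/TRUS
fusion biopsy of suspicious lesions. `promai` implements a complete,
testable version of such a computer-aided analysis pipeline:

1. **Co-registration** of DWI and DCE volumes onto the T2W grid by
   maximizing mutual information over a 9-DoF affine transform
   (translations, rotations, anisotropic scales) with a conjugate-gradient
   ascent.
2. **Functional parameters** per voxel: the apparent diffusion
   coefficient ADC (mm²/s) from a multi-b-value mono-exponential fit
   `S(b) = S₀ e^(−b·ADC)`; the two-compartment Tofts pharmacokinetic
   parameters `Kᵗʳᵃⁿˢ`, `Vₑ` and `k_ep = Kᵗʳᵃⁿˢ/Vₑ` from the DCE series
   `C_t(t) = Kᵗʳᵃⁿˢ ∫₀ᵗ C_p(τ) e^(−k_ep (t−τ)) dτ`; and a robustly
   normalized T2W intensity.
3. **Malignancy Attention Index (MAI)**: a kernel-based model maps the
   five-feature voxel vector to a score in [0, 1] calibrated so Gleason
   grade *g* corresponds to MAI `0.6 + 0.1·(g − 6)` — grade 6 at 0.6,
   grade 10 at 1.0, benign tissue below 0.6. Training is two-phase:
   a pairwise ranking objective with dynamically grown Gaussian kernels,
   then a monotone calibration to the Gleason anchors.
4. **Biopsy-core evaluation**: recorded core trajectories are projected
   into the MAI map; a core is called positive when its profile maximum
   ≥ 0.6 **and** its profile mean clears a swept threshold (default 0.2).
   Predicted lesions (26-connected components, mean MAI > 0.6, volume
   ≥ 0.5 ml) and core pathology combine into patient-level TP/TN/FP/FN.
5. **Diagnostic accuracy**: sensitivity, specificity and accuracy with
   95% Wilson score intervals, the Youden index `J = sens + spec − 1`
   with a combined-bound interval, and a trapezoidal ROC/AUC over the
   mean-MAI threshold sweep {0.15, 0.2, 0.3, 0.4}.

Because clinical data cannot ship with the package, a first-class
**phantom module** simulates seeded mpMRI studies — ellipsoidal prostate,
graded lesions, the 7-b-value DWI protocol {0, 50, 100, 150, 200, 250,
800} s/mm², 9.9 s DCE frames — with full ground truth (label maps, true
parameter maps, injected misregistrations, simulated biopsy sessions with
effective-length shortfall), so every stage is testable end to end.

## Worked example

```python
import numpy as np
from promai import (
    ConfusionCounts, PipelineConfig, run_pipeline, summarize_diagnostics,
)

# statistics layer on a patient-level confusion table
s = summarize_diagnostics(ConfusionCounts(tp=18, fn=3, tn=21, fp=3))
print(s.sensitivity.value_pct, s.sensitivity.ci_pct)   # 85.71 (65.36, 95.02)
print(s.specificity.value_pct, s.specificity.ci_pct)   # 87.5 (69.0, 95.66)
print(s.accuracy.value_pct)                            # 86.67
print(s.youden_pct, s.youden_ci_pct)                   # 73.21 (34.36, 90.67)

# full synthetic-cohort experiment: simulate, train, register, map,
# score cores, summarize
summary = run_pipeline(PipelineConfig(n_patients=6, seed=42))
print({t: r["counts"] for t, r in summary["per_threshold"].items()})
# {'0.15': {'tp': 1, 'fn': 0, 'tn': 5, 'fp': 0}, '0.2': {...}, ...}
```

The sensitivity line reads: 18 of 21 cancer patients were detected
(85.71%), with a 95% Wilson interval from 65.36% to 95.02%. The pipeline
summary gives, per mean-MAI threshold, the patient-level confusion counts
of the simulated cohort.

The same stages are exposed on the command line:

```bash
mai simulate --patients 2 --seed 1 --out scratch/demo   # NIfTI + cores CSV
mai stats --counts 18,3,21,3                            # the numbers above
mai run --patients 6 --seed 42 --out scratch/run        # full pipeline
```

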