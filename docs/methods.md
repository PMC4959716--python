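# Methods

## Scope and data model

All volumes are `VolumeImage`s: a 3D array plus a NIfTI-style 4×4 affine
mapping 0-based voxel indices to millimetres in a right-handed patient
frame. The affine is the single source of geometry truth; spacing,
origin and orientation are derived from it. World coordinates in CSV and
JSON artifacts are mm in that frame.

## Synthetic phantom

The generator renders an ellipsoidal prostate with ellipsoidal lesions
of Gleason grade 6–10 through the same forward models the analysis
inverts. One editable tissue table drives everything; per class it holds
DWI `S₀`, ADC, `Kᵗʳᵃⁿˢ`, `Vₑ`, a T2W base intensity and a DCE baseline.
Defaults follow the qualitative literature pattern (benign peripheral
zone: ADC ≈ 1.6·10⁻³ mm²/s, `Kᵗʳᵃⁿˢ` ≈ 0.05/min; with grade, ADC falls
and `Kᵗʳᵃⁿˢ` rises); they are generator configuration, not claims about
any cohort.

Geometry defaults use the emulated acquisition's pixel sizes and slice
thicknesses (T2W 0.8 × 0.7 × 3 mm, DWI 2.2 × 2.2 × 3 mm, DCE
1.6 × 1.6 × 1.5 mm) on a desk-scale field of view (T2W 64 × 64 × 12,
prostate ≈ 12 ml) so a 30-patient cohort runs in minutes on one CPU.
The DWI b-values are {0, 50, 100, 150, 200, 250, 800} s/mm²; DCE frames
are 9.9 s apart (32 frames by default).

The arterial input function is a delayed biexponential population curve
(amplitudes 3.99/4.78 mM, decays 0.144/0.0111 per minute, 30 s onset) —
a configurable choice, since no AIF is identifiable from the emulated
protocol. DCE signal is baseline + gain·concentration with additive
Gaussian noise; the signal→concentration conversion in the analysis is
the exact inverse (enhancement over the pre-onset baseline divided by
the gain), with the baseline estimated from frames before the AIF onset.

A seeded, smooth multiplicative heterogeneity field (products of
sinusoids in the anatomy's own frame, amplitude 0.15, wavelengths
≈ 2 cm) modulates the T2W intensity and the DWI/DCE baselines. It plays
the role of intra-tissue texture: without it a two-class ellipsoid gives
mutual information almost no rotational signal and no registration
method could recover orientation. Because it scales only baselines, the
decay and pharmacokinetic parameters remain exactly recoverable.

Misregistration is injected by rendering the DWI/DCE anatomy displaced
by a configured 9-DoF transform; ground truth stores the transform, the
label volume and the true parameter maps on the T2W grid.

Biopsy sessions emulate a transperineal template: systematic cores on a
jittered grid across the prostate's axial footprint plus cores targeted
at lesion centres; 16–36 cores per patient (uniform 16–32, mean 24),
nominal throw 17 mm. Each core's *effective length fraction* is drawn
from Beta(8, 2) (mean 0.8) and truncates the segment from the entry —
this reproduces the clinically observed mechanism where a distal lesion
is missed by a short specimen. The pathology result is the maximum truth
grade along the effective segment (0 = negative).

Cohort generation draws patient cancer status i.i.d. at prevalence
46.7%, 1–2 lesions per positive patient with grades {6, 7, 8, 9} at
probabilities {0.3, 0.4, 0.2, 0.1} (grade-7 mode, matching a
median-Gleason-7 population) and semi-axes 4–8 mm. All randomness flows
from one seed; identical spec + seed gives bit-identical output.

### What the phantom does not emulate

Rician noise (noise is Gaussian), bias fields, susceptibility and motion
artifacts, zonal anatomy (peripheral vs. transition zone), infiltrative
lesion margins, and scanner-specific intensity scales. Passing tests
therefore demonstrate correctness of the computational pipeline under
its own forward models — not clinical performance.

## Registration

The secondary volume (DWI or DCE) is aligned to the primary (T2W) by
maximizing histogram mutual information over 9 parameters: translations
(mm), rotations (degrees, composed Rz·Ry·Rx about the primary volume
centre), anisotropic scales. The initial guess uses scanner geometry
only (world origin offset). MI uses 32 equal-width bins spanning each
volume's 1st–99th percentile range (frozen during optimization so the
objective is comparable across transforms), computed over voxels where
the transformed secondary overlaps the primary.

The optimizer is Polak–Ribière(+) nonlinear conjugate gradient with
central finite-difference gradients, a backtracking line search, and
per-parameter scaling (1 mm ≡ 1° ≡ 0.01 scale) so one step size serves
all nine parameters. An iterate is accepted only if it increases MI, so
MI is non-decreasing along accepted iterates; the run stops when the MI
gain falls below 10⁻⁵ nats or after 200 iterations, and a stall (no
uphill step found repeatedly) returns the best-so-far transform with a
warning. Resampling is trilinear with a declared fill value.

On 20 seeded phantoms with random injected transforms (|t| ≤ 5 mm,
|r| ≤ 5°, s ∈ [0.95, 1.05]) the median target-registration error at
prostate-surface points is below the primary grid's mean voxel
dimension; the registration acceptance test asserts exactly that.

## Parametric maps

*ADC*: per-voxel ordinary least squares of ln S on b; ADC = −slope
clamped at 0. Voxels with non-positive samples fit on the positive
subset and are flagged; fewer than two usable samples flags the voxel
with ADC 0.

*Tofts*: the forward model is an exponential-kernel recursion that is
exact for an AIF piecewise linear between frames, making forward and
fit self-consistent. Two fitters share it: `fit_tofts` (per curve)
does bounded nonlinear least squares (`Kᵗʳᵃⁿˢ` ∈ [0, 5]/min,
`Vₑ` ∈ (0, 1]) multi-started from a fixed 3×3 grid ordered by forward
SSE; `fit_tofts_volume` (whole volumes) initializes all voxels at once
with the linearized (integral-equation) least-squares form and refines
with a damped Gauss–Newton iteration vectorized across voxels. Both are
deterministic; identically-zero curves are flagged. Noiseless recovery
is ≤ 10⁻⁴ absolute (typically ~10⁻⁹).

*T2W normalization*: z-score with median and 1.4826·MAD over a
rectangular VOI enclosing the prostate — invariant to positive affine
intensity rescaling; a constant VOI flags the volume and returns zeros.

## Malignancy model

Features per voxel, in fixed order: normalized T2W, ADC, `Kᵗʳᵃⁿˢ`,
`Vₑ`, `k_ep`. Standardization constants are learned at fit time and
stored with the model; features flow through the package raw and are
standardized exactly once, inside the model.

The score is an RBF network: Gaussian activations at learned centres
(width = median pairwise distance of a training subsample, one width
per kernel at creation), a learned projection weight per kernel, and a
fixed unit summation layer — the composition of the two linear layers
of the classic architecture collapses to one learned linear map, which
is what is trained.

*Phase 1 (ordering)*: kernels start at the class means and grow by
error feedback — each round adds a centre at the training sample
involved in the most misordered pairs — while the projection weights
minimize a convex logistic loss on score differences over subsampled
ordered label pairs (≤ 10⁵ per round, seeded) with an L2 penalty.
Growth stops when the held-out ranking error fails to improve for 5
rounds, hits zero, or the kernel cap (64) is reached.

*Phase 2 (calibration)*: with weights frozen, the class-median raw
scores become calibration nodes mapped to the Gleason anchors
0.6 + 0.1·(g − 6), benign at 0.3. Medians are made strictly increasing
(pool-adjacent-violators plus epsilon separation — the ordering phase
makes violations rare), and prediction applies monotone piecewise-linear
interpolation clamped to [0, 1]; raw scores outside the node range take
the end node's MAI. Non-monotone nodes are rejected at model load.

The estimator is scikit-learn style (`fit`, `decision_function`,
`predict`, `get_params`/`set_params`, trailing-underscore fitted
attributes) and serializes to versioned JSON that round-trips exactly.
No trained weights ship with the package; the test suite trains a
seeded reference model from the phantom cohort.

## Core evaluation and patient scoring

Core profiles sample the MAI map every 0.5 mm along the effective
segment, averaging the axial point with four radial offsets at 1 mm
(zero radius available for sensitivity analysis). A core is positive
iff profile max ≥ 0.6 and profile mean ≥ the swept threshold; ties pass
(≥ uniformly). Predicted lesions are 26-connected components above 0.6
with component mean MAI > 0.6 and volume ≥ 0.5 ml. A core belongs to a
lesion if any sample point falls in its component.

Patient scoring: a predicted lesion is *confirmed* if at least one of
its cores is pathology-positive (Gleason ≥ 6) and index-positive;
*disproved* if its cores are all pathology-negative; *unsampled* lesions
are excluded. Any confirmed lesion → TP; no sampled lesions and no
positive pathology → TN; no sampled lesions with positive pathology →
FN; everything else → FP. An exhaustive truth-table test enumerates all
evidence combinations.

## Statistics

Wilson score intervals use the exact two-sided normal quantile
(1.959964 at 95%); this reproduces every published interval bound to
the printed two decimals, including one bound that z = 1.96 misses by
0.01. The Youden interval sums the unrounded Wilson bounds of
sensitivity and specificity and subtracts 100 — a reporting convention
for threshold sweeps, not a standard interval; a seeded percentile
bootstrap is provided as the conventional alternative. Percentages are
rounded half-up to two decimals at reporting only. ROC points are
(1−specificity, sensitivity) with (0,0) and (1,1) appended, sorted, and
integrated by trapezoid.

## Pipeline and problem sizes

`run_pipeline` chains simulate → align → maps → MAI → cores → statistics
and is byte-deterministic for a fixed seed. Registration mode is
`"metadata"` (geometry-only alignment, appropriate when no
misregistration is simulated — the evaluation cohorts) or `"mi"` (full
optimization, exercised by the registration tests). Default problem
sizes — 4 training patients (~500 benign voxels each plus all lesion
voxels), 6-patient demonstration cohorts, 30-patient evaluation cohorts
in the acceptance tests — were chosen so the full suite runs on a
single CPU in a few minutes while leaving the statistical checks
well-powered.

## Known limitations

- Patient-frame orientation is identity in all generated data; oblique
  acquisitions are supported by the data model but not exercised by the
  phantom.
- The MI objective uses hard histogram binning; partial-volume
  interpolation (Parzen windows) would smooth the objective further.
- `fit_tofts_volume`'s Gauss–Newton refinement assumes curves reasonably
  close to the Tofts family; gross model violations fall back to the
  linearized estimate rather than being flagged.
- The Youden interval policy is a reproduction convention (see above);
  use the bootstrap for conventional inference.
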