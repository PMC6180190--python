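# Methods

## The measurement model

Each subject contributes one (right, left) pair per modality, with the pair
ordered to match the scatter-plot convention x = right hippocampus,
y = left hippocampus.

**Normalized hippocampal volume.** Hippocampal voxels are counted per side
in an integer label map (FreeSurfer convention by default: 17 left, 53
right; every code is configurable) and divided by the supratentorial
volume, defined here as all nonzero labels minus a configurable exclusion
list (default: cerebellar cortex/white matter 7, 8, 46, 47 and brainstem
16). Voxel volume cancels in the ratio, so the measure is invariant to
voxel size; the raw mm³ values are kept in provenance. The supratentorial
label-set definition is ours — segmentation tools differ in theirs — and is
logged with every run.

**Relative FLAIR intensity and SUVR.** FLAIR is bias-corrected in native
space, then FLAIR and PET are rigidly registered and resliced onto the T1
grid (intensity images trilinear, masks nearest-neighbour — mixing label
values through interpolation is never acceptable). Each volume is divided
by its mean over the skull-stripped brain mask, which makes the within-mask
mean exactly 1 and renders all downstream ROI statistics invariant to
global intensity scaling — the point of the standardization step, and a
property the test suite checks directly. The per-side measure is the
arithmetic mean of the standardized image over the hippocampal mask. PET
receives no bias correction and neither image is smoothed before ROI
averaging; both choices are recorded in provenance.

## Bias-field correction

The field is modelled as `exp(P(x))` with `P` a 3-D polynomial of total
order 1–4 (default 3) in coordinates normalized to [−1, 1] per axis. `P` is
fitted by least squares to log-intensities inside the brain (or foreground)
mask, mean-centred in the log domain, and the resulting field is rescaled
by a single scalar so the corrected image preserves the within-mask
arithmetic mean exactly. (Log-centring alone — geometric mean 1 — would
inflate the corrected mean by the Jensen gap `exp(σ²/2)`, about 4.6 % at a
log-field RMS of 0.3, so both conventions cannot hold simultaneously; the
arithmetic mean is the one downstream standardization cares about, and the
scalar cancels there anyway.) A polynomial surrogate was chosen over a
generative segmentation-based correction because it is fully specifiable:
the phantom generator produces fields from the same family, so recovery can
be asserted quantitatively (field correlation > 0.99 on a linear-bias
phantom fitted at order 3).

Limitations: anatomy with smooth, large-scale intensity structure is
partially absorbed into the field. On phantoms this is visible as a
percent-level CV reduction even without bias; with a whole-brain mask and
low polynomial order the effect on the (left − right) contrast is
negligible because the model family is smooth and the hippocampi are
compact and mirrored.

## Rigid registration

Six-parameter rigid alignment (3 translations mm, 3 rotations deg about the
fixed image's geometric center, x–y–z extrinsic Euler) maximizing
normalized mutual information (Studholme form, (H(A)+H(B))/H(A,B)) on a
32×32 joint histogram with both intensity ranges clipped at the 1st/99th
percentiles. Multi-resolution: block-averaged pyramids at factors (4, 2, 1).
Both images are presmoothed with a 1-voxel Gaussian; without it the
piecewise-smooth phantoms expose NMI's well-known attraction to
interpolation/noise artifacts, and a wrong pose can genuinely score higher
than the true one. The optimizer is Powell's derivative-free direction-set
method with identity initialization and fixed tolerances (xtol 0.01), which
makes runs bit-reproducible. A Nelder–Mead simplex was evaluated first and
rejected on measurement: in this 6-D landscape it stalls in spurious optima
(rotation errors > 7° on phantoms whose true pose scores better at every
pyramid level), while Powell recovers poses to ~0.01 mm / 0.1°. As a
safeguard the identity transform is returned if it scores better than the
optimum found at full resolution.

Transforms map target-frame world coordinates into the moving frame (the
pull-back convention used by the resampler). Reslicing uses trilinear or
nearest-neighbour interpolation; voxels sampling outside the moving volume
are zero-filled and flagged in an out-of-field mask.

## The control error ellipse

The classifier fits the control sample mean and covariance (n−1
denominator) per modality and thresholds squared Mahalanobis distance at
the χ² quantile with 2 df — the large-sample confidence region of a
bivariate normal. An F-based small-sample prediction-region correction
(`2(n−1)(n+1)/(n(n−2)) · F₂,ₙ₋₂(CL)`) is available behind a flag but off by
default, matching the plug-in χ² convention of the widely used
error-ellipse scripts. Coverage is calibrated: 10⁶ fresh draws from the
fitted normal land inside the CL = 95 % ellipse at 95.0 % ± 0.5 %
(recomputed by `scripts/acceptance.py`).

**Lateralization rule.** Which side to blame is genuinely underdetermined
by an "outside the ellipse" decision, so the package uses the per-modality
pathological z-score: `z = (μ_side − v_side)/σ_side` where a decrease is
pathological (volume, SUVR) and `(v_side − μ_side)/σ_side` where an
increase is (FLAIR); the side with the larger positive z is predicted. If
neither z is positive — the point is abnormal in the healthy direction — or
the two tie exactly, the subject is detected but unlateralizable, which is
scored as wrong (`w`), keeping sensitivity conservative. The rule and the
direction table are logged with every classification.

## Evaluation

Sensitivity = %(code `p`) among patients, specificity = %(inside) among
controls. The CL sweep refits nothing but the threshold (mean and
covariance are CL-independent), evaluates the integer grid 1–99 %, and the
ROC is integrated by trapezoid over (1 − specificity, sensitivity) with
(0, 0) and (1, 1) appended. Youden ties break toward the smallest CL, the
most conservative (largest) normal region among optima. When sensitivity is
computed by resubstitution against an ellipse fitted on the same n
controls, the squared self-Mahalanobis distance is bounded by (n−1)²/n
(≈ 20.05 at n = 22), so 100 % specificity is guaranteed only once the χ²
threshold passes that bound — beyond CL ≈ 99.996 %, outside the integer
grid. Tests of the perfect-separation limit therefore extend the grid with
{99.9, 99.99, 99.999}; the default sweep keeps the 1–99 convention.

Two-sided Fisher's exact p-values follow the probability-mass summation
convention (sum of hypergeometric probabilities not exceeding the observed
table's), with p = 1 by convention when a margin is zero; the test suite
checks agreement with an independent exhaustive enumeration over all tables
with the observed margins (margins ≤ 60). Percentages are rounded to two
decimals for display only.

With lateralization required, the usual ROC label-swap symmetry
(AUC + AUC_swapped = 1 for a fixed score) intentionally breaks — a
wrong-side detection is not a true positive — and under a null cohort the
correct-lateralization requirement roughly halves sensitivity, pushing AUC
below 0.5. Both behaviours are asserted in tests; the second is the
mechanism behind sub-0.5 AUCs seen when a modality carries no lateralizing
signal.

## Synthetic data

**Phantom.** A deliberately miniature brain: a uniform sphere (default
radius 25 mm on a 64³ grid at 1 mm) containing two ellipsoidal
hippocampus-like ROIs mirrored about the mid-sagittal plane (default
semi-axes 11 × 5 × 4 mm, ≈ 920 mm³; recovery tests that need sub-percent
volumetric discretization use 80–96³ grids with realistic ≈ 1,700–3,600 mm³
ROIs). Tissue intensities are piecewise constant per modality, modulated by
a deterministic low-frequency texture inside the brain (even in x, so the
phantom stays bilaterally symmetric; excluded from the ROIs so ROI means
stay analytic). The texture exists because registration is only well-posed
given tissue contrast — a plain sphere is rotationally ambiguous.
Pathology enters as per-side multipliers: atrophy scales the ellipsoid
semi-axes by factor^(1/3), FLAIR boost and PET drop scale ROI intensity.
Degradation of the FLAIR/PET copies: pull-back through a configured rigid
offset (so the transform registration must recover is the stored inverse),
multiplication by an exp-polynomial bias field with prescribed log-RMS
amplitude, and additive Gaussian noise — Gaussian rather than Rician as a
deliberate simplification, sufficient for mean-based ROI statistics.
Ground truth (field, transforms, ROI voxel counts and analytic volumes) is
returned for recovery tests.

What the phantom does **not** model: anatomy beyond two ellipsoids, partial
volume, Rician noise, MR distortion, PET point-spread. Passing recovery
tests therefore demonstrates correctness of the algorithms under their own
assumptions, not clinical performance.

**Cohorts.** Measurement-space simulation: controls are bivariate-normal
per modality (defaults — volume mean 0.004, SD 3.5 × 10⁻⁴; FLAIR 1.30,
SD 0.06; SUVR 1.05, SD 0.05; inter-side correlation 0.5), patients are
control draws displaced on the assigned side along the pathological
direction by `effect × SD`. Defaults mirror the study conditions: 22
controls, 54 patients, two thirds left-sided, and effect sizes graded
(volume 4 SD, FLAIR 1 SD, SUVR 5 SD) to reproduce the qualitative ordering
of the three modalities' accuracy (moderate / poor / high).

**Clinical fixture.** The packaged 54-patient outcome table (per-method
p/n/w codes, ILAE HS subtype, resection side, follow-up months) is shipped
as CSV; aggregating it reproduces every published rate the tests assert
(sensitivities, subtype detection cells, follow-up descriptives, Fisher
comparison pattern).

## Problem sizes and determinism

All simulations are sized for a single CPU: phantoms 64³–96³ voxels,
registration ≈ 20 s per volume pair, the 10⁶-draw coverage experiment ≈ 1 s.
Every stochastic component takes an explicit integer seed
(`numpy.random.default_rng`); registration and evaluation are deterministic
by construction, and identical configurations produce byte-identical
outputs.

## Known limitations

* The supratentorial volume definition is label-set based and will not
  match any particular segmentation tool's internal definition.
* The bias surrogate absorbs smooth anatomy into the field at high orders;
  orders above 3 are rarely advisable with whole-brain masks.
* NMI registration assumes overlapping fields of view and fails (by design,
  with an error) on constant images; it was validated on phantoms, not on
  clinical multi-modal data.
* The ellipse model assumes bivariate normality of control measurements;
  with n = 22 controls the plug-in χ² threshold is slightly liberal — the
  F-correction flag exists for users who prefer the exact prediction
  region.
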