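# Methods

This package reimplements, as a tested pipeline over synthetic data, a 2D-vs-3D
MRI radiomics workflow for skeletal Ewing sarcoma: feature extraction on
original and wavelet-transformed images, ROI-translation reproducibility
analysis with ICC filtering, collinearity/significance feature selection, and
SMOTE-balanced machine-learning prediction of response to neoadjuvant
chemotherapy. The patient MRI data behind the original study are not publicly
deposited, so every analysis here runs on a seeded synthetic cohort whose
statistical structure matches what the workflow assumes; the package's claims
are therefore about the *machinery* (counts, invariances, oracle agreement,
recovery of planted effects), never about the clinical result.

## Synthetic cohort

`synthetic.generate_cohort` produces `n_good + n_poor` patients (default
23 good / 7 poor responders, matching the emulated study's class imbalance).
Each patient has:

- a **tumour mask**: a randomized rotated ellipsoid with radii drawn from
  12–20 mm, perturbed by a smooth Gaussian random field level-set offset,
  hole-filled, reduced to its largest 6-connected component (always
  ≥ 100 voxels);
- two **sequences** (T1, T2) on a 64×64×28 grid with native spacing
  0.8×0.8×4.0 mm. The anisotropic spacing is deliberate: it forces the 2 mm
  isotropic resampling stage to do real work;
- in-mask intensities from a Gaussian random field (unit-variance smoothed
  white noise) with baseline mean 100 (T1) / 150 (T2) and field SD 10, plus
  i.i.d. Gaussian noise (SD 5) and an optional smooth degree-1 multiplicative
  bias field.

Class structure is controlled by one dimensionless knob, `class_effect`:
good and poor responders differ by `±0.5·class_effect` field-SD units in mean
intensity and by `±25%·class_effect` in the field's spatial correlation length
(baseline 6 mm). The mean offset moves first-order statistics (mean, minimum);
the correlation-length difference moves spatial texture (GLCM correlation and
cluster shade, NGTDM strength) — the feature families the selection stage is
meant to recover. `class_effect = 0` makes the two classes exchangeable in
law. T1 and T2 share a common field component (correlation 0.6) so the
sequences are correlated but not redundant.

Noise is Gaussian rather than Rician: at the simulated SNR (~10–30) the two
are close, and the Gaussian model keeps the planted moments invertible in
tests. One global integer seed drives a `SeedSequence` spawn per patient, so
cohorts are bit-reproducible and cases mutually independent.

**What the generator does not emulate:** anatomy (bones, soft-tissue
boundaries), sequence-specific contrast mechanisms, partial-volume effects at
tumour borders, scanner/protocol heterogeneity between centres, or any link
between image texture and true chemotherapy response. Passing tests therefore
demonstrate that the pipeline measures what it claims on data with known
structure — not that the clinical discrimination of the original cohort is
reproducible.

## Pre-processing

Fixed composition order: optional bias-field correction → grey-level
normalization → isotropic resampling → Gaussian denoising, with grey-level
discretization deferred to texture computation. Defaults: 2 mm target
spacing, 32 bins, 1 mm denoising sigma.

- **Normalization** is a plain z-score over the whole volume (no outlier
  clipping, no scale factor); this is the simplest reading of "grey-level
  normalization" and is flagged in the config as an assumption.
- **Resampling** interpolates the image with a cubic B-spline
  (`scipy.ndimage.zoom`, order 3) and the mask with nearest-neighbour, onto a
  shared isotropic grid. On an already-isotropic grid the stage is an exact
  identity, which makes the composed pipeline idempotent there; on
  anisotropic input the interpolation slightly renormalizes the intensity
  moments, which is the only source of non-idempotence.
- **Denoising** uses a physical-units sigma converted per axis, so smoothing
  is isotropic in millimetres even on anisotropic grids.
- **Bias correction** is a stand-in for N4-style inhomogeneity correction:
  a polynomial of total degree ≤ 2 is least-squares fitted to log-intensities
  inside the mask and divided out, with the in-mask mean gain renormalized.
  It is off by default (the generator plants no bias unless asked) and exists
  so the planted-bias recovery path is testable without an external binary.
- **Discretization** uses a fixed bin *count* (32) with bin edges from the
  min/max over mask voxels, per source image — each wavelet sub-band is
  discretized independently. Level = floor((x − min)/width) + 1, max mapped
  to the top bin; constant input collapses to level 1 and is flagged.

Axial = third array axis, everywhere. 2D analysis takes the axial slice with
the largest tumour area (ties to the lowest index).

## Feature inventory

Canonical name grammar: `{mode}|{sequence}|{source}|{class}|{name}`.

Per ROI mode and sequence: 14 mesh-based shape descriptors (original
geometry only), plus 93 descriptors per source image — 18 first-order,
24 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM — with sources = original
image + first-level stationary wavelet sub-bands (8 in 3D, 4 in 2D,
Coiflet-1 by default). Totals: 851 per sequence in 3D and 479 in 2D
(1702 / 958 per patient over both sequences); original-image-only 3D
extraction yields 107.

Design choices worth knowing:

- **Wavelets** use the *undecimated* (stationary) transform so every
  sub-band keeps the input grid and the mask applies without resampling.
  The basis is configurable; Coiflet-1 is the default. Odd axes are
  edge-padded to even length and cropped back.
- **2D shape** reuses the same 14 mesh descriptors on the one-voxel-thick
  volume rather than switching to a planar descriptor set — this is the only
  reading under which the printed inventory (479 = 14 + 93 + 4·93) is
  arithmetically consistent, and it keeps the descriptor list identical
  across modes.
- **Surface mesh**: marching cubes runs on a lightly smoothed indicator
  field (Gaussian, 0.7 voxel) rather than the raw binary mask. The raw
  staircase surface overestimates curved areas by ~9%, which would bias
  sphericity down for every blob; with anti-aliasing, digitized balls reach
  sphericity > 0.98 while mesh volume stays within ~2% of the voxel count
  for tumour-sized masks.
- **Texture matrices**: GLCM symmetrized, distance 1, 13 unique 3D angles
  (4 in 2D), features computed per angle on the normalized matrix and
  arithmetic-averaged over angles; GLRLM likewise. GLSZM zones use full
  (26/8) connectivity; GLDM uses α = 0 at distance 1; NGTDM uses the
  distance-1 neighbourhood mean, excluding voxels with no in-mask
  neighbour. All texture work happens inside the mask bounding box, which
  also makes every feature exactly invariant to whole-voxel translations of
  image + mask together.
- **Degenerate limits** never surface as NaN: a single-grey-level ROI gives
  GLCM correlation 1 and NGTDM strength 0 (each formula's limit), zero
  variance gives skewness/kurtosis 0, and each such case is flagged so the
  ICC stage sees complete matrices plus an explicit degeneracy record.

## Reproducibility analysis

Multiple manual delineations are mimicked by translating the ROI in ±x and
±y (array axes 0 and 1) by `max(1, round(0.10 × bounding-box length))`
voxels — the 1-voxel floor prevents a vacuous perturbation on small masks.
Voxels pushed outside the grid are dropped; a translation that empties the
mask is an error and excludes the case. A perturbation set is always the
original plus exactly 4 translations; for 2D ROIs the in-plane translations
preserve the slice.

Agreement across the five variants is ICC(2,1): two-way random effects,
absolute agreement, single measurement,

    ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE)),

chosen because the same 5 ROI variants play the role of interchangeable
"raters" for every subject. ICC(3,1) is available as a config option and the
model used is recorded in the output. A feature is **stable** iff
ICC > 0.75 strictly; an undefined ICC (zero total variance) counts as
unstable. Stable fractions are reported overall and per group (shape /
first-order / textural / wavelet, parsed from the name grammar), and the 2D
and 3D ICC distributions are compared with a Welch two-sample t-test.

## Feature selection

Applied once on the whole cohort, mirroring the emulated design (a config
flag re-runs it inside each training fold instead; see "Leakage" below).
Zero-variance features are removed first and flagged. Then, while any
surviving pair has Pearson |r| > 0.8, the highest-|r| pair is found and the
member with the larger mean |r| against all currently surviving features is
dropped (ties: lexicographically later name, for determinism). "Mean |r|
over surviving features" is our reading of "higher collinearity with
others"; it is recorded in the output. Survivors are tested with the
two-sided Wilcoxon rank-sum test — exact enumeration when both groups have
≤ 10 members and no ties, otherwise the tie-corrected normal approximation —
and features with p < 0.05 are kept, ranked by p. No multiple-testing
correction is applied (none was used in the emulated design); the report
says so explicitly. The selected count is data-driven; an optional top-k cap
exists, and the pipeline's classification stage falls back to the top 4
features by p (logged) if nothing passes α, so a no-signal run still
produces a metric panel.

## Classification

Stratified 80-20 hold-out, repeated 100 times; the split plan is a function
of labels + seed only, so 2D and 3D analyses share identical partitions.
Per repeat: features are standardized with training-set statistics; the
training minority is oversampled to parity with SMOTE
(x + u·(x_nn − x), u ~ U[0,1], k = 5 nearest minority neighbours, capped at
minority − 1 — with ~5 poor responders per training fold the cap binds);
the test set is never touched by SMOTE or standardization fitting.

Classifiers: 1-NN (Euclidean, unweighted, hard labels), logistic regression
(unpenalized maximum likelihood; on detected separation it falls back to
weak L2, C = 100, flagged), and a seeded 100-tree random forest with √p
features per split. Score-returning classifiers are binarized at the
threshold maximizing balanced accuracy on the *training* scores (lowest
maximizer on ties), applied unchanged to the test set.

Metrics (positive class = good responder, the prevalent class — consistent
with precision near 1 at high prevalence): sensitivity, specificity,
balanced accuracy = (sens + spec)/2, accuracy, precision, and AUC by the
rank statistic over test scores (for the hard-label 1-NN, the two-point ROC
from its 0/1 predictions, flagged as such). A single-class test set leaves
the undefined entries as NaN, excluded from that metric's average — with
stratified splits (the default, chosen precisely so specificity is defined
in every repeat) this does not occur. Per-patient correct-classification
rates over test-set appearances are tallied with an inclusive ≥ 80%
threshold, per classifier and under all classifiers jointly.

### Leakage, and the no-signal baseline

Because selection runs once on the whole cohort before cross-validation,
hold-out estimates inherit a selection-bias optimism: on a cohort with
`class_effect = 0` (no true signal), a handful of the ~1700 uncorrected
rank-sum tests pass by chance, and classifiers built on those
chance-selected features score near the majority-class rate (~0.77) rather
than collapsing to 0.5. The no-signal sanity check asserts exactly this
(accuracy within Monte-Carlo error of the majority rate, AUC well below the
strong-signal regime), and the in-fold selection flag exists for users who
want the unbiased protocol.

## Problem sizes and numerical choices

The analysis scripts run the full study conditions: 30 patients on the
64×64×28 native grid, wavelets on, 5 ROI variants, both modes, 100 hold-out
repeats (minutes on one core). The test suite exercises the same code on
reduced grids (40×40×16, tumour radii 10–14 mm) and, for oracle checks, on
random ≤ 6×6×6 quantized ROIs, with tolerances 1e-9 (texture vs brute-force
enumeration) and 1e-10 (ICC vs explicit ANOVA). Mesh-derived quantities are
float32-limited (~1e-6 relative). Determinism is absolute: identical config
and seed reproduce every CSV byte-for-byte.

## Known limitations

- The synthetic generator's class model is a stand-in, not an estimate of
  the real cohort; no quantitative description of the original intensity
  distributions exists to calibrate against.
- The bias-correction stage is a polynomial fit, not the N4 algorithm; it
  handles the smooth low-order fields the generator can plant, nothing more.
- Real-data results of the emulated study (stable fractions of 77%/65%, its
  specific selected features, its metric table) are data-dependent and not
  reproducible here; the pipeline reproduces the *structure* of those
  outputs and the arithmetic identities within them.
- Wavelet basis and angle-aggregation conventions are explicit, configurable
  assumptions; published tools differ in these defaults and feature values
  are only comparable under matching settings.
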