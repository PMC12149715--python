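# Methods

`csiseg` implements a two-stage auto-segmentation pipeline for organs at
risk (OARs) on whole-body CT, of the kind used for pediatric craniospinal
irradiation planning, together with its evaluation metric and statistical
comparison machinery. Because clinical cohorts cannot ship with a software
package, every stage is exercised on synthetic whole-body phantoms with
exact ground-truth masks; this note describes the models, the parameters
that matter, and what the synthetic results do and do not show.

## Pipeline model

**Stage 1 — DRR localization.** A digitally reconstructed radiograph (DRR)
is a parallel projection of the HU grid: voxels are clamped to a contrast
window, summed along one canonical axis over a half-open slice interval,
and the image is min-max normalized to 0–255 integers (half-to-even
rounding, for bit-stable output). Three scalar windows — lung [−1500, 0],
soft tissue [0, 50], bone [250, 3000] HU — and their 3-channel composite
are supported. A single-class 2D detector finds the organ's bounding box
on two orthogonal DRRs, and the boxes are fused into a 3D ROI:

* *Body structures* (lungs, kidneys, esophagus, spinal canal, vertebral
  bodies, brain, brainstem): detection on the full coronal DRR, then on a
  sagittal DRR summed only over the coronal box's lateral extent. The ROI
  takes x from the coronal box and y, z from the sagittal box, then grows
  by an organ-specific margin in the axial plane only (+20 px lungs, +15 px
  spine/vertebral bodies/kidneys/esophagus, +10 px brain/brainstem). The
  superior–inferior extent is deliberately not margin-expanded: the margin
  is an axial-plane context allowance, and z precision comes from the
  sagittal detection.
* *Head structures* (eyes, lenses, optic nerves, chiasm, cochleae): the
  head region runs from the volume top to the brainstem's inferior border
  (at inference, from the brainstem's own localization). Left/right half
  sagittal DRRs of the head are built by splitting at the body's lateral
  centroid column; only the bone window is used. Reference boxes are scaled
  ×2 about their center for context. The organ's laterality selects the
  half image; midline organs (the chiasm) use the full lateral extent,
  since a half image would truncate them. Detection order is sagittal
  (z, y candidates) then an axial DRR summed over the detected z-range
  (y, x). Head ROIs get no extra margin — the ×2 box already carries it.

ROIs are clamped to the volume and, where they exceed the organ's maximum
crop size, shrunk symmetrically about their center. Maximum crop sizes are
calibrated from the training cohort (per-organ ROI maxima plus slack) and
stored in the organ config.

**The detector** is pluggable behind a small contract (`fit` on (DRR, box)
pairs, `predict` one box or "not found"); any 2D single-class detector can
drive the pipeline. The shipped implementation is a compact convolutional
box predictor: a tiny U-Net scores each pixel's probability of lying inside
the organ's box, and the prediction is the bounding box of the largest
8-connected thresholded component, with the mean inside-probability as its
confidence. It runs on 2× average-pooled DRRs (`downscale=2`), which both
regularizes and speeds up training; box coordinates are mapped back to full
resolution at the contract boundary (worst-case quantization ±1 px, far
below the axial margins). A heatmap-plus-bounding-box predictor was chosen
over direct coordinate regression because it trains reliably from a dozen
images; the contract keeps the pipeline model-agnostic. A mask-backed
*oracle detector* (predicts the reference box exactly) is used in tests to
validate the fusion geometry independently of any trained model.

**Stage 2 — organ-specific segmentation.** The ROI is cropped into a
*mini-CT*, intensity-clipped, mapped linearly to [0, 1], and zero-padded
symmetrically to the organ's uniform input size. Normalization precedes
padding so the pad value 0 coincides with the clip minimum and the network
sees a constant background. Clip ranges:

* body organs: lo = min(P10 inside the reference mask, P10 in a 2 mm rim
  around it), hi = max(P90 inside, P90 rim). The rim is a morphological
  dilation by an ellipsoidal structuring element with per-axis radii
  ⌈2 mm / spacing⌉, minus the mask. Degenerate (constant) ranges are
  widened by ±1 HU. Because no reference mask exists at inference,
  per-case training ranges are aggregated to an organ-level range by the
  median of the lo and hi bounds and frozen in the organ config.
* head organs: a fixed 0–250 HU window.

Three U-Net variants segment axial slices: a basic encoder–decoder with
skip connections; an attention variant that gates each skip with additive
attention (α = σ(ψ(relu(Wx·x + Wg·g))), 1×1 convolutions, gate signal from
the upsampled decoder path); and a 2.5D variant — the basic 2D network with
3 input channels holding the target slice between its superior and inferior
neighbors (edge slices replicate the missing neighbor). Depth and width are
configurable (`widths`, default (8, 16, 32): two poolings, so axial dims
must be divisible by 4). Training uses soft-Dice + binary cross-entropy
loss with Adam; augmentation applies, with probability 0.5, an
in-axial-plane rotation uniform in ±15° and isotropic scaling uniform in
±15% about the slice center (linear interpolation for the image, nearest
for the mask, same transform for both). Predictions pass through a sigmoid,
are thresholded at 0.5, reduced to the largest 26-connected component
(exact size ties keep the component containing the lexicographically
smallest (z, y, x) voxel), and pasted back into the whole-body frame.

The networks run on a small reverse-mode automatic-differentiation core
written for this package (numpy, float32, im2col convolutions); gradients
are verified against finite differences in the test suite, and training is
bit-reproducible on CPU for a fixed seed. Loss, optimizer, learning rate
and epoch counts live in `TrainConfig`; defaults (lr 3e-3, 30–40 epochs at
phantom scale) were chosen for stable convergence on the phantom tasks.

## Preprocessing and conventions

Volumes live in canonical (z, y, x) order — z superior→inferior, y
anterior→posterior, x patient-left→right — converted once at NIfTI load
from any orthogonal on-disk orientation. Shared preprocessing: voxels
outside the body contour are set to −1000 HU; the body mask, when not
provided, is derived by thresholding at −300 HU (config key), keeping the
largest 26-connected component and filling holes slice-wise; patients are
centered on a fixed axial canvas (default 512 × 256, lateral × AP) by
mapping the body-mask centroid (floored) to the canvas center; overlapping
labels are made mutually exclusive by cropping the smaller structure out of
the larger one; resampling uses nearest-neighbor interpolation for the
image as well as the masks, so masks stay binary and no new HU values are
invented. Heterogeneous inputs are resampled to a fixed target spacing by
default (a fixed matrix size is equally supported through the same
operation).

## Evaluation and statistics

The Dice similarity coefficient is DSC = (2|A∩B| + ε) / (|A| + |B| + ε)
with ε = 1e-7, computed in 3D; the smoothing term keeps the ratio defined
(and equal to 1) when both masks are empty. Report tables give mean ± SD
per organ × model × cohort; the SD is the population standard deviation, so
a single record reports 0 rather than NaN.

The comparison protocol over DSC tables:

* Kruskal–Wallis H across models per organ, Holm–Bonferroni-corrected
  across organs (α = 0.05); Dunn's rank-based pairwise z-tests post hoc for
  surviving organs, reported unadjusted within the organ's family (a config
  switch enables within-family Holm adjustment). Adjusted p-values are
  clipped to 1.
* Mann–Kendall trend of DSC with age per model × organ, Benjamini–Hochberg
  FDR across the batch (α = 0.05). The implementation is the original test:
  S from pairwise signs, tie-corrected variance, continuity-corrected
  normal z, and the tie-corrected tau-b statistic. Records are stably
  sorted by age before testing.
* On a detected trend, a two-sided Mann–Whitney U between the < 10 and
  ≥ 10 year groups (age exactly 10 falls in the older group, following the
  interval notation); validation-vs-test cohort comparisons use
  Mann–Whitney U per model × organ with FDR. scipy selects the exact
  distribution for small tie-free samples and the tie-corrected normal
  approximation otherwise.

## The synthetic phantom

Each phantom is a geometric caricature of a whole-body pediatric planning
CT on a (Z, Y, X) = (96, 96, 160) canvas at 2 mm isotropic spacing
(a scaled-down stand-in for 512 × 256 axial matrices at ≈1 mm): an
elliptical soft-tissue torso stack (≈30 HU), neck and head sphere in −1000
HU air; lung ellipsoids (−800 HU); an air trachea tube (−900 HU) adjacent
to an esophagus-like soft-tissue tube; a vertebral column (+700 HU) with
embedded spinal-canal analog; kidneys (30 HU) wrapped in a −100 HU fat rim
whose thickness grows with age — the kidneys are intentionally
intensity-matched to the body so that the fat plane is the only cue, the
same cue discussed for age-dependent kidney visibility in clinical
segmentation; and a head with brain, brainstem, paired eyes (lenses
inside), optic-nerve tubes meeting at a chiasm, and +500 HU cochlea
analogs. An unlabeled skull shell and orbital sockets give the bone window
a head outline, since head localization uses the bone window only. A
synthetic age covariate (years) multiplies all organ linear sizes by
0.70 + 0.30·age/18 — linear in the cube root of target volume — so organ
voxel counts grow strictly monotonically with age; the fat rim thickens
linearly with age. Organ centers are jittered (drawn before any
age-dependent quantity, so one seed places organs identically at any age);
Gaussian HU noise (SD 5) is added inside the body. Masks overlap only for
declared containment pairs (lens ⊂ eye, spinal canal ⊂ vertebral bodies,
brainstem ∩ brain).

What the phantoms do **not** emulate: anatomical shape variability beyond
size and position, scanner physics (beam hardening, partial volume, noise
texture), pathology, posture, or inter-observer contour variability.
Passing the end-to-end tests therefore shows that the pipeline mechanics —
window selection, projection geometry, box fusion, crop bookkeeping,
normalization, training loop, post-processing, statistics — are correct
and that the models can learn intensity- and context-separable structures;
it does not certify clinical segmentation accuracy.

## Problem sizes and numerical choices

The packaged study runs at desk scale: 16 phantoms (12 train / 4 held
out), detectors trained 150 epochs (batch 32 default; the full-data batch
at this cohort size) on half-resolution DRRs, segmenters 30 epochs on
axial slices of the organ's uniform crop. At these sizes the held-out DSC
is ≈0.99 for the kidney analog (all three variants) and ≈0.82–0.91 for the
eye analog. Other choices: min-max DRR normalization is per-image (window
sums depend on body thickness, so a global scale would not transfer across
patients); all-constant projections map to all-zero images so empty crops
are representable; equal-size component ties and box-confidence ties break
deterministically (lexicographic / smaller index); detector "not found" is
recorded per organ and patient rather than raised, so cohort runs complete.

`scripts/acceptance.py --seed N --out results.json` reruns the whole study
from scratch — cohort simulation, detector and segmenter training for the
kidney analog (all three variants) and eye analog, held-out DSC, oracle
containment over 10 fresh phantoms, and trend-test calibration (null
false-positive rate and planted-trend power over 200 replicates, n = 27
patients per test, matching a validation-cohort size) — in roughly six
minutes on one CPU.

## Known limitations

* The detector is adequate for high-contrast phantom structures; real CT
  would need a stronger detector behind the same contract (the design is
  deliberately model-agnostic).
* The exact clinical U-Net layer configuration is not reproduced; depth
  and width are configurable instead.
* 3D (volumetric) segmentation variants, DICOM/RT-Struct input, surface
  distance metrics and dosimetric evaluation are out of scope.
* The percentile clip rule is defined per case at training time; whether
  to pool per-case or per-organ is an open modeling choice — the median
  aggregation used here is one defensible answer, stored explicitly in the
  organ config so it can be overridden.
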