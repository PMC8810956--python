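# Methods

## Problem and approach

After image-guided thermal ablation of hepatocellular carcinoma, local
tumor progression (LTP) appears on follow-up contrast CT as a small
arterially enhancing nodule at the margin of the hypodense ablation
zone.  `ltpdetect` implements a patch-based detection pipeline for this
finding: a Hounsfield-unit (HU) volume is re-windowed into three 8-bit
channels chosen to make the ablation zone and enhancing nodules
conspicuous, fixed-size 3D patches are sampled around candidate
locations, a small 3D convolutional network classifies each patch, an
operating threshold is chosen on a validation split, and above-threshold
patches are reported as bounding-box region proposals on the axial
slices.

## Multi-window channels

Each channel is the standard radiology display transform
`clamp(round(255·(HU − WL + WW/2)/WW), 0, 255)` with round-half-up:

| channel | window | WL (HU) | WW (HU) | rationale |
|---|---|---|---|---|
| red | liver | 60 | 400 | global anatomy |
| green | ablation | 80 | 60 | separates hypodense ablation zone from parenchyma |
| blue | tumor | 120 | 40 | saturates only for arterially enhancing tissue |

The three channels are re-windowings of one arterial-phase volume, so
"registration" is identity alignment; no resampling occurs and the
composed volume inherits the source geometry exactly.  The rounding rule
is not dictated by the display standard; round-half-up is used and
isolated in one function so the choice is pinned by tests.

## Patch sampling

Patches are 32×32 voxels in-plane × 8 axial slices × 3 channels.  For an
even depth there is no central slice; the stack spans `z−4 … z+3`
(biased low).  Per annotated lesion center `p`, 20 positives are drawn
by re-sampling the in-plane window with uniform integer jitter
`|Δ| ≤ 12` per axis, so `p` always stays ≥ 4 voxels inside the
footprint.  Negatives come at 40 per case — twice the per-lesion
positive rate — either (lesion-bearing cases) rejection-sampled so every
center lies strictly farther than 15 voxels (Euclidean, all three axes)
from every lesion center, or (control cases) uniformly over the volume
interior restricted to a body mask (HU > −500).  The exclusion radius is
interpreted in voxels and kept in `SamplingConfig` so a millimetre-based
radius is a one-line change.  Lesions without 8-slice axial headroom
raise an error naming the case; padding would fabricate HU values.

Valid patch centers span the half-open interval `[16, n−16)` in-plane
and `[4, n_z−3)` axially; the screening grid (`grid_candidates`) uses
the same intervals, which on a 512×512×40 volume with strides 32/8
yields the 15·15·5 = 1125 interior candidates the tests pin.

Augmentation acts on the axial plane only and identically on every slice
and channel: horizontal flip, shift ≤ 4 px, shear ≤ 10°, zoom 0.9–1.1,
rotation ≤ 15°, each applied with probability ½ (magnitudes uniform).
Bilinear interpolation with edge replication is used; outputs are
re-quantized to uint8.

## Network and training

The classifier is a deliberately small 3D CNN, implemented in NumPy
inside the package (`ltpdetect._nn`) with explicit forward/backward
passes (im2col convolutions evaluated as BLAS matrix products):

    input 3@8×32×32
    conv 3×3×3 (same) → 16@8×32×32 → ReLU → maxpool 2×2×2
    conv 3×3×3 (same) → 32@4×16×16 → ReLU → maxpool 2×2×2
    conv 3×3×3 (same) → 64@2×8×8   → ReLU
    flatten 8192 → dense 512 → ReLU → dense 128 → ReLU → dense 1 → sigmoid

Exactly two pooling stages are used: the printed stage shapes
(16@8×32×32 → 32@4×16×16 → 64@2×8×8) force pooling after the first two
convolutions only, which `infer_stage_shapes` propagates analytically
and a forward pass confirms.  Inputs are scaled to [0, 1]; loss is
binary cross-entropy on the sigmoid output (the natural pairing);
class imbalance is handled by the sampling ratios, not loss weights.

Training hyperparameters (He initialization; Adam, learning rate 1e-3;
batch 32; early stopping on validation loss with patience 10 within a
100-epoch budget) are package defaults — the architecture constrains the
model, not the optimizer — and every field is carried in `TrainConfig`
and logged.  Max-pool subgradients are shared equally among tied
maxima.  Runs are reproducible for a fixed seed up to BLAS reduction
order.  Training and validation patches must come from disjoint cases;
the model object enforces this when case identifiers are present.

## Threshold selection and metrics

The operating point maximizes the mean of sensitivity and specificity
(equivalently the Youden index) on validation probabilities.  Candidate
cuts are the midpoints between consecutive distinct probabilities plus
the two boundary cuts; prediction is positive when probability ≥
threshold; ties prefer higher specificity, then the larger cut.  On a
separable validation set this returns the midpoint of the gap.

Sensitivity, specificity, PPV and accuracy come from integer confusion
counts; a zero denominator flags the metric as undefined instead of
propagating NaN.  ROC-AUC and step-summed average precision are computed
via scikit-learn and cross-checked in tests against exhaustive
pair-counting and a manual step-sum.  Confidence intervals are
Clopper–Pearson (exact beta quantiles) for proportions and DeLong for
the AUC — standard substitutes, since the method definitions behind the
reference implementation were not published; the DeLong placement
computation is verified against an O(mn) double loop.

Note one arithmetic fact pinned by tests: on a 160/640 test composition
the confusion counts uniquely consistent with sensitivity 96.88% and PPV
91.18% are (tp, fp, tn, fn) = (155, 15, 625, 5), whose plain accuracy is
97.50% (no integer solution yields 97.59%) and whose specificity is
625/640 = 97.66% to two decimals.  The package computes plain
ratios and does not chase the published rounding.

## Region proposal

Candidate centers are stored in a dictionary keyed by patch id when
patches are cut; after prediction, every patch with probability ≥
threshold becomes a proposal carrying its probability unchanged (no
re-scoring), the 32×32 in-plane box centered on its footprint, its slice
number, and the z-range of its 8-slice stack.  Proposals are sorted by
descending probability and are not merged — no non-maximum suppression
is applied, matching the candidate-level definition of the task.
Rendering draws the boxes on the composed RGB slices (clipping only for
display) across the full 8-slice stack of each proposal.  The
whole-volume screening grid is an extension for annotation-free use; the
canonical evaluation scores pre-extracted candidates.

## Synthetic phantoms

The phantom generator makes the pipeline testable without patient data.
A case is a liver-like parenchyma block (default 128×128×40 voxels at
0.7×0.7×3.0 mm, within the 3–5 mm slice-thickness regime of abdominal
CT) holding:

* a hypodense ablation sphere (default radius 15 mm, 40 HU) at the
  volume center;
* 0–n enhancing lesion spheres (default diameter 12 mm, 120 HU) whose
  centers sit on the ablation-sphere surface with ±2 mm radial jitter —
  the imaging definition of LTP at the ablative margin;
* bright tubular vessels (150 HU, radius 2 mm, roughly axial with random
  tilt) as the distractor class that drives false positives in practice;
* additive Gaussian HU noise (default sd 10) applied after structure
  placement, so each recorded lesion-center voxel holds exactly the
  lesion HU pre-noise.

Default HU values satisfy the ordering `ablation < parenchyma < lesion ≤
vessel` and place lesions inside the tumor window (100–140 HU); they are
geometric choices, not fits to patient statistics, because no HU
distributions for LTP or ablation zones were available.  The generator is
bit-deterministic per seed.

Cohorts assign cases (never patches) to train/validation/test.  The
reference cohort reproduces the published data distribution — 34
lesion-bearing cases carrying 49 lesions (15 with two) split 21/5/8 with
lesion totals 36/5/8, and 40 controls split 27/5/8 — via a greedy
assignment that satisfies both the case and lesion split counts exactly;
with the default sampling rates this yields 980 positive patches
(720/100/160), 1,360 lesion-case negatives and 1,600 control negatives,
with a test set of 160 positives + 640 negatives.

What the phantoms do **not** emulate: real anatomy and texture,
contrast-phase kinetics, scanner noise spectra, arterioportal shunts,
and reader variability in annotation.  Passing the end-to-end bars
(held-out AUC ≥ 0.95, lesion hit rate ≥ 0.9) therefore demonstrates that
the pipeline's plumbing, sampling rules, optimization and thresholding
work as specified on a signal of realistic geometry — not that the
classifier reaches any particular accuracy on patient CT.

## Problem sizes

The bundled runs are sized for a single CPU: the reference-cohort count
check uses compact 72×72×24 phantoms (the arithmetic is
resolution-independent); the end-to-end run in the acceptance script
trains on a 26-case cohort (16 LTP / 10 controls, one lesion each,
~1,240 patches) for up to 12 epochs, and the test-suite variant is
slightly smaller.  These sizes are the package's own defaults for a
desk-scale demonstration; all of them are parameters.

## Known limitations

* The NumPy network trains on CPU only and is intentionally minimal; it
  reproduces the architecture, not any published learned weights.
* Exclusion radius in voxels mixes anisotropic axes (15 voxels spans
  10.5 mm in-plane but 45 mm axially at default spacing); kept because
  the radius is defined in index space.
* Phantom lesions are uniform spheres; a classifier could exploit
  simpler cues than real LTP presents.
* DICOM reading covers single-series axial CT with rescale tags;
  non-axial acquisitions are rejected rather than resampled.
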