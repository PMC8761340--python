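# Methods

`mvseg` implements automatic segmentation of head-and-neck primary tumors on
multi-sequence MRI with a multi-view ("2.5D") convolutional network, together
with the surrounding pipeline: template-space construction, two-step rigid
registration, class-rebalanced patch sampling, soft-dice training,
cross-validated evaluation, and a phantom generator that supplies ground truth
in place of clinical data.  This note records the model, the parameters that
matter, and the design choices made where more than one reading was possible.

## Standard space and registration

A study-specific template is built from co-registered T1-weighted volumes by
voxel-wise *non-zero* averaging: per voxel, occupancy is the fraction of
volumes with a non-zero intensity there; voxels with occupancy ≥ 0.30 (the
`occupancy_threshold`) form the **occupancy mask**, inside which the template
value is the mean over the non-zero contributors, zero elsewhere.  The
occupancy mask doubles as the pipeline's body mask: it defines which voxels
count as tissue for sampling and inference, since no other tissue mask exists
in the design.

Cases enter the template frame by a two-step scheme per sequence:

1. a 12-dof affine registration of the moving image to the fixed image;
2. a 6-dof rigid registration initialized with the **rigid component** of
   step 1 (the orthogonal polar factor of its 3×3 block, translation kept) and,
   for the T1-to-template step, weighted by the occupancy mask so background
   cannot drive the metric.

STIR and contrast-enhanced T1 are registered to their own subject's T1 the
same way, and transforms are concatenated (4×4 homogeneous matrices in world
millimetres, moving → fixed).  Registration runs on SimpleITK: negative
normalized correlation for same-contrast pairs, Mattes mutual information (50
bins) across sequences, a 3-level multiresolution pyramid (shrink 4/2/1,
smoothing 2/1/0 mm), regular-step gradient descent (initial step 2.0,
relaxation 0.6, minimum step 1e-4, ≤150 iterations per level) and a
deterministic regular-grid 25% metric sample.  On phantoms this recovers rigid
perturbations up to 10 mm / 10° to ≈0.03 mm and ≈0.2°, comfortably inside the
0.5 mm / 0.5° recovery contract the tests enforce, at about 4 s per two-step
on one CPU.  Template construction is affine-only by design: the averaging and
occupancy logic — the bespoke computation — is exact, while deformable
refinement is out of scope.  Labels always travel with nearest-neighbour
interpolation (spline interpolation of a binary mask would produce non-binary
values); intensities travel with B-spline interpolation.

## Patch sampling and normalization

Roughly 2% of in-mask voxels are tumor in a realistic cohort, so training
draws a fixed-size sample without replacement: `round(0.5 · N_tumor)` tumor
voxels and `round(0.01 · N_healthy)` healthy voxels (in-mask, non-tumor).
Fixed counts rather than Bernoulli draws make the contract exactly testable.
At 2% prevalence these fractions yield an approximately balanced training set;
this coupling matters (see the phantom section).

Each sequence is variance-normalized per case over the body mask — z-scored
and clipped to ±4 SD — before patches are cut; a missing contrast channel is
all zeros, as is a constant image.  Around a selected voxel, six 32×32×3
patches are extracted (channels T1, T1gad, STIR): axial, coronal and sagittal
planes at scale 0 (32×32, the voxel at in-window index (16,16), window
[c−16, c+15]) and scale 1 (64×64 centered the same way, then 2×2
mean-pooled to 32×32 — exactly mean-preserving).  The full image is zero-padded
by 32 voxels per side so border patches stay full-sized.

## Network and training

Six independent branches — one per (view, scale), no weight sharing — each
apply one convolutional block (3×3 kernels, spatial batch normalization, ReLU),
2×2 max pooling, 25% dropout, and a dense layer; the branch outputs are
concatenated and fused by two dense layers ending in a 2-way softmax
(non-tumor, tumor).  Widths default to 8 convolution filters, 32 branch-dense
units and 64 head units — sized for single-CPU phantom experiments; they are
plain configuration fields (`ModelConfig`) since no canonical values exist for
them.  Initialization is He-style from a seeded generator, so builds are
bit-reproducible.

The loss is the binary soft dice over the whole batch,

    L = 1 − (2 Σᵢ pᵢ gᵢ + ε) / (Σᵢ pᵢ + Σᵢ gᵢ + ε),  ε = 1e-7,

with pᵢ the tumor-class probability.  Optimization is Adam (β₁ = 0.9,
β₂ = 0.999, ε = 1e-8), batch size 512 (final partial batch kept), 25 epochs by
default, initial learning rate 1e-3 multiplied by 0.8 at epochs 5, 10, 15, 20
(0-based): `lr(e) = 1e-3 · 0.8^⌊e/5⌋`.  An epoch is one shuffled pass over the
voxels sampled once per fold (sampling is a dataset-construction step, not
re-done per epoch).  Cross-validation is 5-fold, stratified on (volume group ×
tumor location) with seeded round-robin assignment, so every case is held out
exactly once and never influences the model that scores it.

The network is implemented directly on NumPy arrays with explicit forward and
backward passes; the branch hot path (im2col, fused BN+ReLU+pool and its
backward, patch gathering) runs through numba kernels that are exact
re-expressions of the layer math.  A float64 pure-NumPy reference path is kept
and cross-checked against both the kernels and central finite differences in
the test suite.  Batch normalization uses batch statistics during training and
running averages (momentum 0.9, ε = 1e-5) at inference, making inference
deterministic and batch-size independent.

## Inference and evaluation

Full-volume segmentation applies the trained network to every voxel of the
occupancy mask; a voxel is tumor iff its tumor probability is strictly greater
than 0.5 (the p = 0.5 tie maps to non-tumor — an explicit rule, since argmax
alone does not define ties).  No post-processing is applied: no
connected-component filtering, no hole filling.  Predicted volume is voxel
count × voxel volume.

Spatial agreement is the Dice similarity coefficient, 2|A∩B|/(|A|+|B|),
defined as 1.0 when both masks are empty so the function is total.  Volumetric
agreement is the intraclass correlation, single measure, absolute agreement,
two-way random effects —

    ICC(2,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE)),  k = 2,

computed from the explicit two-way ANOVA mean squares, per fold, and
summarized as mean ± SD across folds (the ± form of a per-fold quantity).  DSC
is summarized across cases (primary) and additionally across fold means.
Cases stratify into four volume groups with closed upper boundaries — V1 ≤ 3,
3 < V2 ≤ 7, 7 < V3 ≤ 15, V4 > 15 cm³ — and by T-stage, N-stage and location;
subgroup DSC distributions are compared with the two-sided Wilcoxon rank-sum
test (exact enumeration when both groups have ≤ 20 tie-free observations,
otherwise the normal approximation with midrank ties), with no
multiple-testing correction, α = 0.05.

## Phantoms

Each phantom is a smoothed ellipsoidal body with low-frequency Gaussian
texture, a radial shading gradient, and three asymmetric internal structures
(a bright spine-like rod, a dark airway-like tube, an oblique muscle-like
blob).  The asymmetries are load-bearing: a plain textured ellipsoid is nearly
rotationally symmetric and leaves rigid rotation unidentifiable to any
intensity metric.  The tumor is a perturbed-ellipsoid blob whose voxel count is
matched to the target volume by quantile thresholding (within 5%, single
6-connected component), placed at a site-dependent position.  Contrast follows
the clinical pattern the network must exploit: near-isointense on T1 (+5),
strongly hyperintense on STIR (+60), enhancing on contrast T1 (+50), over body
baselines of order 100, with Gaussian noise (SD 2) added inside the body.
Non-T1 sequences can be perturbed by known rigid motions (default 2 mm / 2°)
and the whole subject can be posed away from the template frame; the generator
returns the exact realigning transforms and the template-frame ground-truth
mask.  The contrast channel is dropped with probability 0.03, mirroring its
real-world availability.

The default grid is 64³ at **2 mm** spacing.  The spacing is deliberate: it
gives a ~12 cm body of ≈550 cm³, so tumors in the 2–20 cm³ range occupy ≈2% of
in-mask voxels — the prevalence regime the 50%/1% rebalancing was designed
for, under which the sampled training set is roughly balanced.  At 1 mm the
same grid would make tumors ~13% of the body; after rebalancing the training
set is then ~90% tumor and the soft-dice optimum degenerates to the all-tumor
map.  Cohorts draw per-stratum target volumes (V1: 1.5–3, V2: 3.5–6.5, V3:
8–14, V4: 16–22 cm³), cycle tumor locations, and are deterministic under a
seed.  The full 224×192×117 @ 1 mm template grid remains a configuration
choice for real data.

What the phantoms do *not* model: MR physics (no bias fields, partial-volume
mixing, vendor differences), deformable anatomy, multi-focal or infiltrative
tumors, pathological lymph nodes, and inter-subject anatomical variability
beyond jittered ellipsoid axes.  Passing tests therefore demonstrate that the
*mechanism* — registration, sampling, learning, inference, scoring — recovers
known ground truth under clean, well-contrasted conditions; they say nothing
about clinical accuracy on real MRI.

## Problem sizes used by the tests and the acceptance script

The end-to-end experiments run 12-phantom cohorts (64³ @ 2 mm), train reduced
models (5 epochs, default widths) on 9 cases and segment 3 held-out cases;
the overfit check trains on one phantom for up to 40 epochs; registration
recovery uses 20 known perturbations across 5 phantoms; the CLI-chain
determinism check uses four 40³ phantoms with a 1-epoch, 2-filter model.
These sizes were chosen so the whole suite runs on one desktop CPU core.

## Known limitations

- Template construction is affine-only; anatomical sharpness of a deformably
  refined template is not reproduced.
- The similarity metrics (normalized correlation / Mattes MI) are stated
  choices; other metrics would give slightly different registrations.
- Per-volume (not per-patch) normalization is a stated reading of an ambiguous
  convention; both interpretations share the ±4 SD clip.
- ICC across folds with k = 5 has wide sampling variance for small cohorts;
  folds with fewer than 3 cases are skipped with a warning.
- The NumPy/numba network is single-threaded; wall-clock scales linearly in
  sampled voxels and mask size.
- Boundary localization is limited by the architecture: after 2×2 max
  pooling, the center voxel of a patch is aliased with its immediate
  neighbours inside one pooled block, so segmentations carry a roughly
  one-voxel over-inclusion shell (false positives hug the tumor surface,
  false negatives are rare).  On coarse phantom grids, where that shell is a
  third or more of the tumor volume, per-case DSC saturates around 0.8–0.87
  even for a memorized phantom; the effect shrinks with voxel size relative
  to tumor radius.
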