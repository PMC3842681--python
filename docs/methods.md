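# Methods

## The problem

Delineating lymph-node target volumes on CT for radiotherapy planning is
slow and operator-intensive. Atlas-based auto-segmentation registers one or
more previously contoured patients (atlases) onto a new patient image and
transfers their contours; multi-atlas methods then *fuse* the resulting
segmentation proposals into a single consensus proposal that an oncologist
edits. `atlasfuse` implements one such fusion rule — probabilistic
weighting fusion (PWF) — together with its evaluation metrics and a
synthetic ensemble generator, so the whole pipeline can be exercised and
tested at desk scale without clinical data or a commercial registration
engine.

## Probabilistic weighting fusion

Inputs are a target image `T` and N proposals, each a deformed atlas image
`A_i` with a deformed binary structure mask `M_i`, all resampled to the
target grid.

**Similarity.** Registration success for atlas *i* is summarized by the
Pearson-type normalized cross-correlation (NCC) between `T` and `A_i`
over a region of interest consisting of `M_i` dilated by a uniform physical
margin (default 10 mm; 50 mm suits large pelvic node regions). Dilation
thresholds the exact Euclidean distance transform, so margins are true
millimetre distances on anisotropic grids. Each atlas is scored in its own
structure-plus-margin ROI.

**Weights.** Let `m_i` be the similarity of atlas *i*. The latent
segmentation quality is modelled as

    q_i = (k/s) · m_i + ε_i ,   ε_i ~ N(0, 1) i.i.d.,

where the single ratio k/s measures how strongly registration quality
(as seen by the image similarity) predicts segmentation quality relative to
quality's intrinsic spread. The fusion weight is the probability that atlas
*i* is the best:

    w_i = P(q_i = max_j q_j)
        = ∫ φ(t) Π_{j≠i} Φ(t + (k/s)(m_i − m_j)) dt .

The integral is evaluated by Gauss–Hermite quadrature (64 nodes by
default), with the product accumulated in log space (`log_ndtr`) and the
weight vector renormalized to absorb quadrature error. The model has the
two defining limits built in: k/s = 0 gives equal unbiased weights 1/N and
k/s → ∞ selects the single most similar atlas. Only similarity
*differences* enter, so weights are invariant to shifting all similarities
by a constant. At N = 2 the closed form `w_1 = Φ((k/s)(m_1 − m_2)/√2)`
provides an exact test point, and for N ≤ 4 the quadrature is
cross-checked against direct Monte-Carlo simulation of the model.

**Fusion.** Each mask is converted to a signed Euclidean distance map
(negative inside, positive outside, voxel-center-to-voxel-center distances
in mm, no truncation). The fused structure is the zero sublevel set of the
convex combination `Σ_i w_i · SDF_i` — a weighted mean shape. Exact zero
is background, a strict and testable tie rule.

Weights are one scalar per atlas, not per voxel: locality comes from the
structure-plus-margin ROI over which similarity is measured.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `k_over_s` | 0.5 | quality-vs-similarity coupling; 0.5 suits low-contrast head-and-neck-like settings, 20 the prostate-like setting where similarity is informative |
| `margin_mm` | 10 | ROI dilation margin (mm); 50 for large pelvic regions |
| `quadrature_nodes` | 64 | Gauss–Hermite nodes; ≥ 32 enforced |

Optimizing k/s from training data is deliberately out of scope; the two
defaults are carried as documented operating points.

### Degenerate inputs

* Empty or all-foreground masks have no surface; the distance transform
  refuses them. An everywhere-nonnegative fused map yields an empty mask
  with a warning rather than an error.
* A proposal whose ROI has zero intensity variance cannot be scored; it is
  kept in the ensemble with similarity `min(scoreable) − 0.1` and a logged
  warning, so it receives near-zero weight at large k/s and 1/N at k/s = 0.
* Tie similarities need no tie-breaking — equal inputs get equal weights by
  symmetry of the integrand.

### Numerical notes

* Weights below ~1e-300 underflow to exact zero at extreme k/s
  separations; monotonicity of weights in similarity is strict only above
  underflow.
* The fused mask is invariant to permuting (proposal, weight) pairs up to
  voxels whose combined distance value is exactly at the zero level, where
  float summation order can flip the strict threshold. Such exact ties do
  not occur for the smooth distance combinations the pipeline produces.

## Evaluation metrics

* **DSC** `2|A∩B|/(|A|+|B|)` over voxels, with the voxel-center membership
  rule. Both-empty is defined as 1, exactly-one-empty as 0; the clinical
  workflow never meets the former.
* **Volume** is member-voxel count × voxel volume, with no partial-volume
  modelling — the simplest auditable rule; clinical systems differ in their
  partial-voxel handling, so absolute volumes are system-dependent anyway.
* **Volume ratio** candidate/reference, and a batch evaluator that emits
  one `(case, method)` row per candidate as CSV.

## Synthetic ensemble generator

The deformable-registration step of the clinical pipeline (done with a
commercial engine in practice) is replaced by *forward simulation*, which
provides ground truth for free.

**Phantom.** The structure is a union of 1–3 ellipsoids; the default is an
elongated two-lobe union (semi-axes 14×12×10 mm each, overlapping along an
oblique axis) on a 64³ grid at 1 mm isotropic spacing — a stand-in for an
elongated nodal region. The image is `contrast · indicator + correlated
background texture + white noise`. Defaults: contrast 25, texture
amplitude 30 with 30 mm correlation length, noise σ 5 (arbitrary units).
The regime is deliberately low-contrast with smooth, long-range background
structure: nodal regions on CT are soft-tissue targets that barely differ
from their surroundings (which is why atlas methods are used at all),
embedded in anatomy that correlates over centimetres. In this regime NCC
differences between proposals are modest — the operating point at which a
k/s of order 10–20 is a meaningful calibration rather than a winner-take-all
switch.

**Deformations.** Registration error is emulated by smooth random
displacement fields: i.i.d. normal control-point displacements on a 16 mm
lattice, cubic-spline interpolated to the voxel grid. Per-proposal
registration sigmas are drawn uniformly from 1–8 mm (a modelling choice —
no quantitative error distribution is available for the clinical setting).
Images are warped by backward mapping with trilinear interpolation; masks
are warped through their signed distance map and re-thresholded, avoiding
nearest-neighbour label aliasing.

**What the image can and cannot see.** Each proposal's mask is warped by
the registration field *plus* an independent anatomy-difference field
(default σ 3 mm) that does not touch the proposal image. This reflects how
deformable registration behaves in homogeneous soft tissue: the optimizer
aligns intensities almost perfectly (the aperture problem leaves no
gradient signal inside uniform tissue), while the structure inherited from
a different subject keeps an irreducible shape error that image similarity
cannot detect. Consequently (i) NCC ranks the registration-error component
statistically rather than deterministically, and (ii) even the best-scoring
proposals disagree with one another — precisely the conditions under which
similarity-weighted shape averaging improves on individual proposals and
concentrates the fused shape on the common core (the volume-shrinkage
effect).

**Noise coupling.** Image noise added to a warped proposal grows linearly
with its registration sigma (`0.5 + 0.25·σ`), a mild coupling that keeps
image decorrelation dominated by the misalignment itself while ensuring
worse registrations also look worse.

**Acquisition independence.** Proposal images are warps of the *noise-free*
phantom plus their own noise realization; sharing the target's observation
noise would let a well-registered proposal score a spuriously perfect NCC.

**What the generator does not emulate:** real CT anatomy and Hounsfield
calibration, registration failure modes that are systematic rather than
random (e.g. sliding interfaces), inter-observer contour variability, and
multi-structure context. Passing tests on these phantoms demonstrate the
internal consistency and the qualitative mechanics of the method — not
clinical accuracy on patient data.

## Problem sizes used in tests and the acceptance script

Oracle comparisons (signed distance, dilation, DSC) run on hundreds of
random masks within 8³ grids, where O(n²) all-pairs brute force is exact
and fast. Ensemble experiments use 20 seeded runs of N = 15 proposals on
64³ phantoms — the N of the pelvic setting at a grid size that keeps a full
20-run experiment in a few CPU-minutes. End-to-end CLI checks use a 40³
phantom with N = 3.

## Known limitations

* Axis-aligned grids only; oblique direction cosines are rejected at read
  time rather than resampled.
* Weights are global per atlas; truly local (per-voxel or per-region)
  weighting is out of scope.
* No surface-distance metrics (Hausdorff, mean surface distance) and no
  statistical cohort comparisons.
* The distance transform is voxel-center exact but has no sub-voxel
  surface model; digitization error is ~half a voxel at the boundary.
* Byte-identical reproducibility across runs holds for uncompressed
  outputs (`.nii`, `.mha`); gzip containers embed a timestamp in their
  header, so `.nii.gz` files are content-identical but not byte-identical.
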