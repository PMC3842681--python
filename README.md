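# atlasfuse

Multi-atlas segmentation fusion by **probabilistic weighting fusion (PWF)**
of signed distance maps, for radiotherapy structure auto-segmentation
workflows — plus the evaluation metrics (Dice similarity coefficient,
structure volumes) and a synthetic deformation-phantom generator that
stands in for the deformable-registration engine, so the method can be
run, tested and studied on a laptop.

## Who this is for

Researchers and medical-physics developers working on atlas-based
auto-segmentation of lymph-node target volumes (head-and-neck, pelvic),
who need a transparent, testable reference implementation of
similarity-weighted shape fusion and its evaluation.

## The method

Given a target image `T` and N atlas proposals — deformed atlas images
`A_i` with deformed structure masks `M_i` on the target grid:

1. **Similarity**: `m_i = NCC(T, A_i)` over `M_i` dilated by a uniform
   physical margin (10 mm default; 50 mm for large pelvic regions).
2. **Weights**: model segmentation quality as `q_i = (k/s)·m_i + ε_i` with
   `ε_i ~ N(0,1)` i.i.d.; weight each atlas by the probability it is best,

       w_i = ∫ φ(t) Π_{j≠i} Φ(t + (k/s)(m_i − m_j)) dt ,

   evaluated by Gauss–Hermite quadrature. `k/s = 0` gives equal weights;
   `k/s → ∞` selects the single most similar atlas. Defaults: 0.5
   (head-and-neck-like), 20 (prostate-like).
3. **Fusion**: the fused structure is the zero sublevel set of
   `Σ_i w_i · SDF(M_i)` — the weighted mean shape of the proposals.

Evaluation follows voxel-center semantics: DSC `2|A∩B|/(|A|+|B|)` and
volume = voxel count × voxel volume.

See `docs/methods.md` for the model assumptions, parameter rationale, what
the synthetic generator does and does not emulate, and numerical details.

## Worked example

Fusion weights from the command line (three atlases, prostate-like
`k/s = 20`):

```sh
$ atlasfuse weights --similarities 0.92,0.88,0.75 --k-over-s 20
0.71273, 0.284872, 0.00239779
```

The most similar atlas dominates but does not win outright; the clearly
worse third atlas is effectively excluded.

A full synthetic experiment in Python:

```python
import numpy as np
from atlasfuse import PhantomSpec, PWFConfig, make_ensemble, pwf_fuse, dice, volume

target, truth, proposals, manifest = make_ensemble(PhantomSpec(seed=0), n_atlases=15)
result = pwf_fuse(target, proposals, PWFConfig(k_over_s=20.0, margin_mm=20.0))

print("fused DSC  %.3f   mean individual %.3f"
      % (dice(result.fused_mask, truth),
         np.mean([dice(p.mask, truth) for p in proposals])))
print("fused vol  %.0f  mean individual %.0f  truth %.0f"
      % (volume(result.fused_mask),
         np.mean([volume(p.mask) for p in proposals]), volume(truth)))
```

prints

```
fused DSC  0.871   mean individual 0.637
fused vol  13580  mean individual 14117  truth 13908
```

The fused proposal overlaps the ground truth far better than the average
individual proposal (DSC 0.87 vs 0.64), and its volume falls below the
individual mean — the characteristic shrinkage of distance-map averaging,
which emphasizes the core common to most proposals.

The same pipeline runs from the shell: `atlasfuse simulate` writes a
phantom target, ground truth, proposals and a manifest CSV;
`atlasfuse fuse` consumes the manifest and writes the fused mask plus a
JSON report of per-atlas similarities and weights; `atlasfuse evaluate`
produces a `case_id,method,dsc,volume_mm3,volume_ratio` CSV.

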