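"""Per-atlas registration-success scores.

Registration quality is approximated by the Pearson-type normalized
cross-correlation (NCC) between the target image and a deformed atlas
image, evaluated over the deformed structure dilated by a uniform
physical margin (10 mm is the head-and-neck default; 50 mm suits large
pelvic regions).  Each atlas is scored in its own structure-plus-margin
region of interest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateROIError, ParameterError
from .volumes_io import AtlasProposal, BinaryMask, ImageVolume, assert_common_grid

__all__ = ["SimilarityScore", "dilate_mask", "ncc", "score_proposal"]


@dataclass(frozen=True)
class SimilarityScore:
    """NCC of one atlas against the target over its dilated-structure ROI."""

    atlas_id: str
    ncc: float
    roi_voxel_count: int
    margin_mm: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.ncc <= 1.0:
            raise ValueError(f"ncc must lie in [-1, 1], got {self.ncc}")
        if self.roi_voxel_count < 2:
            raise ValueError("ROI must contain at least 2 voxels")
        if self.margin_mm < 0:
            raise ValueError("margin must be nonnegative")


def dilate_mask(mask: BinaryMask, margin_mm: float) -> BinaryMask:
    """Dilate by a physical margin: include every voxel whose center lies
    within ``margin_mm`` (Euclidean, mm) of some foreground voxel center.

    Uses the exact Euclidean distance transform rather than a voxel-unit
    structuring element so anisotropic grids behave correctly; the result
    is a superset of the input and is clipped at the grid bounds.
    """
    if margin_mm < 0:
        raise ParameterError(f"dilation margin must be nonnegative, got {margin_mm}")
    m = mask.membership
    if not m.any():
        raise ParameterError("cannot dilate an empty mask")
    if margin_mm == 0 or m.all():
        return BinaryMask(mask.geometry, m.copy())
    dist_to_fg = ndimage.distance_transform_edt(~m, sampling=mask.geometry.spacing)
    return BinaryMask(mask.geometry, dist_to_fg <= margin_mm)


def ncc(target: ImageVolume, moving: ImageVolume, roi: BinaryMask) -> float:
    """Pearson-type normalized cross-correlation over the ROI voxels.

    ``sum((a - mean a)(b - mean b)) / sqrt(sum (a - mean a)^2 * sum (b - mean b)^2)``
    with the sums over ROI voxels only; symmetric in its two images and
    invariant to positive affine intensity rescaling of either.

    Raises
    ------
    DegenerateROIError
        If the ROI has fewer than 2 voxels or either image is constant
        within it (the fusion driver maps this to a minimal similarity).
    """
    assert_common_grid([target, moving, roi])
    sel = roi.membership
    n = int(sel.sum())
    if n < 2:
        raise DegenerateROIError(f"ROI must contain at least 2 voxels, got {n}")
    a = target.intensities[sel].astype(np.float64)
    b = moving.intensities[sel].astype(np.float64)
    a -= a.mean()
    b -= b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0.0:
        raise DegenerateROIError("zero intensity variance inside the ROI")
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


def score_proposal(
    target: ImageVolume, proposal: AtlasProposal, margin_mm: float
) -> SimilarityScore:
    """Score one proposal: NCC over its own mask dilated by ``margin_mm``."""
    assert_common_grid([target, proposal.image, proposal.mask])
    roi = dilate_mask(proposal.mask, margin_mm)
    value = ncc(target, proposal.image, roi)
    return SimilarityScore(
        atlas_id=proposal.atlas_id,
        ncc=value,
        roi_voxel_count=roi.voxel_count,
        margin_mm=float(margin_mm),
    )
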