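"""Segmentation evaluation: Dice similarity coefficient, structure volume,
volume ratios and batch evaluation tables.

Voxel semantics follow the voxel-center rule: a voxel belongs to a structure
iff its center is inside.  Volumes are pure voxel counts times the voxel
volume, with no partial-volume handling — the simplest auditable rule.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateMaskError, GridMismatchError
from .volumes_io import BinaryMask, assert_common_grid

__all__ = ["dice", "volume", "volume_ratio", "evaluate_batch", "summarize_records"]

logger = logging.getLogger(__name__)

#: Canonical method labels for evaluation tables.
METHODS = ("manual", "single_atlas", "fused_atlas", "edited_single", "edited_fused", "other")


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|) over voxels.

    Ranges from 0 (no overlap) to 1 (perfect match).  Defined as 1.0 when
    both masks are empty and 0.0 when exactly one is empty.
    """
    assert_common_grid([a, b])
    na, nb = a.voxel_count, b.voxel_count
    if na == 0 and nb == 0:
        return 1.0
    inter = int(np.count_nonzero(a.membership & b.membership))
    return 2.0 * inter / (na + nb)


def volume(mask: BinaryMask) -> float:
    """Structure volume in mm³: member voxel count times voxel volume."""
    return mask.voxel_count * mask.geometry.voxel_volume_mm3


def volume_ratio(candidate: BinaryMask, reference: BinaryMask) -> float:
    """volume(candidate) / volume(reference); the reference must be non-empty."""
    if reference.is_empty():
        raise DegenerateMaskError("volume_ratio requires a non-empty reference mask")
    return volume(candidate) / volume(reference)


def evaluate_batch(
    cases: Sequence[tuple[str, BinaryMask, Mapping[str, BinaryMask]]]
) -> pd.DataFrame:
    """Evaluate candidate masks against per-case references.

    Each case is ``(case_id, reference_mask, {method: candidate_mask})``;
    the result has one row per (case, method) with columns
    ``case_id, method, dsc, volume_mm3, volume_ratio``.  A case whose grids
    mismatch or whose reference is degenerate is logged and skipped; the
    batch continues.
    """
    rows = []
    for case_id, reference, candidates in cases:
        for method, candidate in candidates.items():
            try:
                rows.append(
                    {
                        "case_id": case_id,
                        "method": method,
                        "dsc": dice(candidate, reference),
                        "volume_mm3": volume(candidate),
                        "volume_ratio": volume_ratio(candidate, reference),
                    }
                )
            except (GridMismatchError, DegenerateMaskError) as exc:
                logger.warning("skipping case %r method %r: %s", case_id, method, exc)
    return pd.DataFrame(rows, columns=["case_id", "method", "dsc", "volume_mm3", "volume_ratio"])


def summarize_records(records: pd.DataFrame) -> pd.DataFrame:
    """Per-method mean and median of DSC, volume and volume ratio."""
    return (
        records.groupby("method")[["dsc", "volume_mm3", "volume_ratio"]]
        .agg(["mean", "median"])
        .reset_index()
    )
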