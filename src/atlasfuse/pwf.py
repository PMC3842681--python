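"""Probabilistic weighting fusion (PWF).

Each atlas proposal i carries a similarity score m_i (NCC against the
target).  The latent segmentation quality of proposal i is modelled as

    q_i = (k/s) * m_i + eps_i,        eps_i ~ N(0, 1) independent,

where the single ratio k/s couples registration quality (similarity) to
segmentation quality relative to its expected spread.  The fusion weight
of proposal i is the probability that it is the best proposal,

    w_i = P(q_i = max_j q_j)
        = Integral phi(t) * Prod_{j != i} Phi(t + (k/s)(m_i - m_j)) dt,

evaluated by Gauss-Hermite quadrature and renormalized.  Two limits pin
the model down: k/s = 0 gives equal, unbiased weights (1/N each), and
k/s -> infinity selects the single most similar registration.  Only the
difference m_i - m_j enters, so weights are invariant to adding a
constant to all similarities.

The fused segmentation is the weighted mean shape: the convex combination
of the proposals' signed distance maps, thresholded at zero.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import log_ndtr

from .distance_maps import mask_from_distance, signed_distance, weighted_distance_sum
from .errors import DegenerateROIError, ParameterError
from .similarity import SimilarityScore, score_proposal
from .volumes_io import AtlasProposal, BinaryMask, ImageVolume, assert_common_grid

__all__ = ["PWFConfig", "FusionResult", "compute_weights", "fuse_proposals", "pwf_fuse"]

logger = logging.getLogger(__name__)

#: Similarity penalty assigned to proposals whose ROI cannot be scored.
DEGENERATE_SIMILARITY_PENALTY = 0.1


@dataclass(frozen=True)
class PWFConfig:
    """Tunable parameters of probabilistic weighting fusion.

    ``k_over_s`` is the ratio of the proportionality of segmentation
    quality to registration quality (k) to the expected spread of
    segmentation quality (s); only the ratio is ever used.  Default 0.5
    (head-and-neck setting); 20 suits the prostate setting.  ``margin_mm``
    is the uniform dilation margin of the NCC region of interest.
    """

    k_over_s: float = 0.5
    quadrature_nodes: int = 64
    margin_mm: float = 10.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.k_over_s) or self.k_over_s < 0:
            raise ParameterError(f"k_over_s must be finite and >= 0, got {self.k_over_s}")
        if self.quadrature_nodes < 32:
            raise ParameterError("quadrature_nodes must be >= 32")
        if self.margin_mm < 0:
            raise ParameterError("margin_mm must be nonnegative")


@dataclass
class FusionResult:
    """Fused mask plus the per-atlas similarities and weights that produced it."""

    fused_mask: BinaryMask
    weights: np.ndarray
    similarities: list[SimilarityScore]
    config: PWFConfig

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if len(self.weights) != len(self.similarities):
            raise ValueError("one weight per similarity required")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be nonnegative and sum to 1")

    def report(self) -> dict:
        """JSON-serializable run record (validates against the shipped schema)."""
        from .metrics import volume

        return {
            "config": {
                "k_over_s": self.config.k_over_s,
                "quadrature_nodes": self.config.quadrature_nodes,
                "margin_mm": self.config.margin_mm,
            },
            "atlases": [
                {
                    "atlas_id": s.atlas_id,
                    "ncc": s.ncc,
                    "roi_voxel_count": s.roi_voxel_count,
                    "weight": float(w),
                }
                for s, w in zip(self.similarities, self.weights)
            ],
            "fused_volume_mm3": volume(self.fused_mask),
        }


def compute_weights(
    similarities: Sequence[float], k_over_s: float, quadrature_nodes: int = 64
) -> np.ndarray:
    """Fusion weights: probability each proposal is best under the PWF model.

    Evaluates ``w_i = Integral phi(t) Prod_{j != i} Phi(t + (k/s)(m_i - m_j)) dt``
    with ``quadrature_nodes``-point Gauss-Hermite quadrature; the products are
    accumulated in log space (``log_ndtr``) so that strongly separated
    similarities underflow gracefully, and the result is renormalized to
    absorb quadrature error.
    """
    m = np.asarray(similarities, dtype=np.float64)
    if m.ndim != 1 or m.size == 0:
        raise ParameterError("similarities must be a non-empty 1D sequence")
    if not np.all(np.isfinite(m)):
        raise ParameterError("similarities must be finite")
    if not math.isfinite(k_over_s) or k_over_s < 0:
        raise ParameterError(f"k_over_s must be finite and >= 0, got {k_over_s}")
    n = m.size
    if n == 1:
        return np.ones(1)
    if k_over_s == 0.0:
        return np.full(n, 1.0 / n)

    # Gauss-Hermite: Integral e^{-x^2} f(x) dx ~ sum w_k f(x_k);
    # substitute t = sqrt(2) x to integrate against the standard normal pdf.
    nodes, quad_w = np.polynomial.hermite.hermgauss(quadrature_nodes)
    t = math.sqrt(2.0) * nodes  # (K,)
    delta = k_over_s * (m[:, None] - m[None, :])  # (N, N)
    log_cdf = log_ndtr(t[None, None, :] + delta[:, :, None])  # (N, N, K)
    idx = np.arange(n)
    log_cdf[idx, idx, :] = 0.0  # exclude j == i from the product
    log_prod = log_cdf.sum(axis=1)  # (N, K)
    w = (np.exp(log_prod) @ quad_w) / math.sqrt(math.pi)
    total = w.sum()
    if total <= 0:
        raise ParameterError("weight quadrature collapsed; check inputs")
    return w / total


def fuse_proposals(
    proposals: Sequence[AtlasProposal], weights: Sequence[float]
) -> BinaryMask:
    """Weighted superposition of the proposals' signed distance maps.

    The fused mask is the zero sublevel set of the convex combination; an
    everywhere-nonnegative combination yields an empty mask with a warning
    rather than an error.
    """
    proposals = list(proposals)
    if not proposals:
        raise ParameterError("fuse_proposals requires at least one proposal")
    assert_common_grid([p.mask for p in proposals])
    sdms = [signed_distance(p.mask) for p in proposals]
    fused = weighted_distance_sum(sdms, weights)
    return mask_from_distance(fused)


def pwf_fuse(
    target: ImageVolume,
    proposals: Sequence[AtlasProposal],
    config: PWFConfig = PWFConfig(),
) -> FusionResult:
    """End-to-end probabilistic weighting fusion.

    Scores every proposal by NCC over its dilated structure, converts the
    scores to weights under ``config.k_over_s``, and fuses the masks by
    weighted distance-map superposition.  A proposal whose ROI cannot be
    scored (zero intensity variance) is kept in the ensemble with a
    similarity of ``min(scoreable) - 0.1`` and a logged warning, so it
    receives near-zero weight at large k/s and the uniform 1/N at k/s = 0.
    """
    proposals = list(proposals)
    if not proposals:
        raise ParameterError("pwf_fuse requires at least one proposal")
    assert_common_grid([target] + [p.mask for p in proposals] + [p.image for p in proposals])

    raw: list[SimilarityScore | None] = []
    for p in proposals:
        try:
            raw.append(score_proposal(target, p, config.margin_mm))
        except DegenerateROIError as exc:
            logger.warning("proposal %r has a degenerate ROI (%s); penalizing", p.atlas_id, exc)
            raw.append(None)

    scored = [s.ncc for s in raw if s is not None]
    if not scored:
        raise DegenerateROIError("no proposal could be scored (all ROIs degenerate)")
    fallback = min(scored) - DEGENERATE_SIMILARITY_PENALTY

    similarities: list[SimilarityScore] = []
    for p, s in zip(proposals, raw):
        if s is None:
            roi_n = max(p.mask.voxel_count, 2)
            s = SimilarityScore(
                atlas_id=p.atlas_id,
                ncc=max(-1.0, fallback),
                roi_voxel_count=roi_n,
                margin_mm=float(config.margin_mm),
            )
        similarities.append(s)

    weights = compute_weights(
        [s.ncc for s in similarities], config.k_over_s, config.quadrature_nodes
    )
    fused = fuse_proposals(proposals, weights)
    if fused.is_empty():
        warnings.warn("fused mask is empty", stacklevel=2)
    return FusionResult(fused_mask=fused, weights=weights, similarities=similarities, config=config)
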