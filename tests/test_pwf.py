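"""The probabilistic weighting model: limits, closed form, Monte-Carlo cross-check."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from atlasfuse import (
    AtlasProposal,
    BinaryMask,
    GridGeometry,
    ImageVolume,
    ParameterError,
    PWFConfig,
    compute_weights,
    dice,
    fuse_proposals,
    pwf_fuse,
)
from conftest import ball_mask, random_proper_mask


def monte_carlo_weights(m, k_over_s, n_samples, seed=0):
    """Independent oracle: sample q_i = (k/s) m_i + eps_i and count argmax wins."""
    rng = np.random.default_rng(seed)
    m = np.asarray(m, float)
    q = k_over_s * m + rng.standard_normal((n_samples, m.size))
    wins = np.bincount(np.argmax(q, axis=1), minlength=m.size)
    return wins / n_samples


def test_zero_k_over_s_gives_uniform_weights():
    rng = np.random.default_rng(0)
    for _ in range(10):
        m = rng.uniform(-1, 1, size=rng.integers(1, 20))
        w = compute_weights(m, 0.0)
        np.testing.assert_allclose(w, 1.0 / len(m), atol=1e-12)


def test_huge_k_over_s_selects_best():
    w = compute_weights([0.95, 0.90, 0.85], 1e6)
    np.testing.assert_allclose(w, [1.0, 0.0, 0.0], atol=1e-6)


def test_two_atlas_closed_form():
    # P(q1 > q2) = Phi(k/s * (m1 - m2) / sqrt(2)) for two unit-variance normals
    w = compute_weights([0.9, 0.8], 10.0)
    expected = norm.cdf(10.0 * 0.1 / np.sqrt(2.0))
    assert w[0] == pytest.approx(expected, abs=1e-6)
    assert w.sum() == pytest.approx(1.0, abs=1e-12)


def test_equal_similarities_share_weight_equally():
    w = compute_weights([0.4, 0.4, 0.4, 0.4], 17.3)
    np.testing.assert_allclose(w, 0.25, atol=1e-9)


@pytest.mark.parametrize("n", [2, 3, 4])
def test_quadrature_matches_monte_carlo(n):
    rng = np.random.default_rng(n)
    m = rng.uniform(0.5, 1.0, size=n)
    k_over_s = 5.0
    n_samples = 1_000_000
    mc = monte_carlo_weights(m, k_over_s, n_samples, seed=n)
    w = compute_weights(m, k_over_s)
    se = np.sqrt(mc * (1 - mc) / n_samples)
    assert np.all(np.abs(w - mc) <= 3 * se + 1e-12)


def test_weights_monotone_in_similarity():
    rng = np.random.default_rng(42)
    for _ in range(20):
        m = rng.uniform(-1, 1, size=8)
        w = compute_weights(m, rng.uniform(0.1, 30))
        order = np.argsort(m)
        assert np.all(np.diff(w[order]) >= -1e-12)
        # strict where similarities differ, unless both weights have
        # underflowed to zero at large k/s separations
        dw = np.diff(w[order])
        dm = np.diff(m[order])
        above_underflow = w[order][1:] > 1e-12
        assert np.all(dw[(dm > 1e-9) & above_underflow] > 0)


def test_weights_invariant_to_similarity_shift():
    m = np.array([0.2, 0.5, 0.9])
    w0 = compute_weights(m, 7.0)
    w1 = compute_weights(m + 123.4, 7.0)
    np.testing.assert_allclose(w0, w1, atol=1e-9)


def test_weights_continuous_at_small_k_over_s():
    w = compute_weights([0.1, 0.9, 0.5], 1e-8)
    np.testing.assert_allclose(w, 1.0 / 3.0, atol=1e-6)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    k_over_s=st.floats(0.0, 100.0, allow_nan=False),
)
def test_weights_are_a_probability_vector(seed, k_over_s):
    rng = np.random.default_rng(seed)
    m = rng.uniform(-1, 1, size=int(rng.integers(1, 16)))
    w = compute_weights(m, k_over_s)
    assert np.all(w >= 0)
    assert w.sum() == pytest.approx(1.0, abs=1e-9)


def test_compute_weights_input_validation():
    with pytest.raises(ParameterError):
        compute_weights([], 1.0)
    with pytest.raises(ParameterError):
        compute_weights([0.5, np.nan], 1.0)
    with pytest.raises(ParameterError):
        compute_weights([0.5], -1.0)


def _proposal(geom, mask, image=None, atlas_id="p"):
    if image is None:
        image = ImageVolume(geom, np.zeros(geom.shape))
    return AtlasProposal(atlas_id, image, mask)


def test_fuse_single_proposal_identity(unit_grid):
    rng = np.random.default_rng(1)
    mask = random_proper_mask(rng, unit_grid)
    fused = fuse_proposals([_proposal(unit_grid, mask)], [1.0])
    np.testing.assert_array_equal(fused.membership, mask.membership)


def test_fuse_identical_masks_any_weights(unit_grid):
    rng = np.random.default_rng(2)
    mask = random_proper_mask(rng, unit_grid)
    props = [_proposal(unit_grid, mask, atlas_id=f"p{i}") for i in range(3)]
    fused = fuse_proposals(props, [0.2, 0.5, 0.3])
    np.testing.assert_array_equal(fused.membership, mask.membership)


def test_fuse_concentric_balls_gives_mid_radius():
    geom = GridGeometry((64, 64, 64))
    center = (31.5, 31.5, 31.5)
    props = [
        _proposal(geom, ball_mask(geom, center, 10.0), atlas_id="small"),
        _proposal(geom, ball_mask(geom, center, 20.0), atlas_id="large"),
    ]
    fused = fuse_proposals(props, [0.5, 0.5])
    assert dice(fused, ball_mask(geom, center, 15.0)) >= 0.98


def test_pwf_fuse_single_proposal_ignores_k(unit_grid):
    rng = np.random.default_rng(3)
    mask = random_proper_mask(rng, unit_grid)
    target = ImageVolume(unit_grid, rng.normal(size=unit_grid.shape))
    prop = AtlasProposal("only", ImageVolume(unit_grid, rng.normal(size=unit_grid.shape)), mask)
    for k in (0.0, 0.5, 50.0):
        res = pwf_fuse(target, [prop], PWFConfig(k_over_s=k, margin_mm=2.0))
        np.testing.assert_array_equal(res.fused_mask.membership, mask.membership)
        assert res.weights == pytest.approx([1.0])


def test_pwf_fuse_permutation_equivariance(unit_grid):
    rng = np.random.default_rng(9)
    target = ImageVolume(unit_grid, rng.normal(size=unit_grid.shape))
    props = []
    for i in range(4):
        mask = random_proper_mask(rng, unit_grid, p=0.3)
        img = ImageVolume(unit_grid, target.intensities + rng.normal(0, 0.5 + i, unit_grid.shape))
        props.append(AtlasProposal(f"p{i}", img, mask))
    config = PWFConfig(k_over_s=5.0, margin_mm=2.0)
    res = pwf_fuse(target, props, config)
    perm = [3, 1, 0, 2]
    res_p = pwf_fuse(target, [props[i] for i in perm], config)
    np.testing.assert_allclose(res_p.weights, res.weights[perm], atol=1e-12)
    np.testing.assert_array_equal(res_p.fused_mask.membership, res.fused_mask.membership)


def test_pwf_fuse_degenerate_roi_gets_minimum_similarity(unit_grid):
    rng = np.random.default_rng(10)
    target = ImageVolume(unit_grid, rng.normal(size=unit_grid.shape))
    mask = random_proper_mask(rng, unit_grid, p=0.3)
    good = AtlasProposal("good", ImageVolume(unit_grid, target.intensities + 0.1), mask)
    flat = AtlasProposal("flat", ImageVolume(unit_grid, np.zeros(unit_grid.shape)), mask)
    res = pwf_fuse(target, [good, flat], PWFConfig(k_over_s=20.0, margin_mm=2.0))
    sims = {s.atlas_id: s.ncc for s in res.similarities}
    assert sims["flat"] == pytest.approx(sims["good"] - 0.1)
    assert res.weights[0] > res.weights[1]


def test_fusion_report_validates_against_schema(unit_grid):
    from atlasfuse.schema import validate_report

    rng = np.random.default_rng(11)
    target = ImageVolume(unit_grid, rng.normal(size=unit_grid.shape))
    mask = random_proper_mask(rng, unit_grid, p=0.3)
    prop = AtlasProposal("a", ImageVolume(unit_grid, target.intensities + 0.05), mask)
    res = pwf_fuse(target, [prop], PWFConfig(margin_mm=2.0))
    report = res.report()
    validate_report(report)
    broken = dict(report, fused_volume_mm3="big")
    with pytest.raises(ValueError, match="schema"):
        validate_report(broken)
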