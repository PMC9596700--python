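"""The gaze-strategy model: scale weights, masks, sampling, penalties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gazehmm import autodiff as ad
from gazehmm.faces import build_pyramid
from gazehmm.gaze import (
    AttentionMaskSet,
    Fixation,
    GazeStrategy,
    ROI,
    apply_masks,
    attention_masks,
    attention_mask_tensor,
    center_bias_penalty,
    sample_fixation_sequence,
    scale_weights,
    scale_weights_tensor,
)
from conftest import gradcheck


def _reference_strategy(spatial_sd=4.0, saccade=3.0, image_size=64):
    rois = []
    for mean in ([20.0, 24.0, 0.0], [44.0, 24.0, 1.0], [32.0, 40.0, 2.0]):
        cov = np.diag([spatial_sd**2, spatial_sd**2, 0.25])
        rois.append(ROI(mean=np.array(mean), covariance=cov))
    return GazeStrategy(rois=rois, saccade_noise_sd=saccade, image_size=image_size)


# -- scale weights -----------------------------------------------------------

def test_scale_weights_symmetric_at_middle_level():
    for temp in (0.2, 0.5, 1.5):
        w = scale_weights(1.0, temp)
        assert w[0] == pytest.approx(w[2])
        assert w.sum() == pytest.approx(1.0)


def test_scale_weights_hard_assignment_limit():
    w = scale_weights(0.0, temperature=1e-3)
    assert np.allclose(w, [1.0, 0.0, 0.0], atol=1e-12)


def test_scale_weights_ratios_match_gaussian_responsibilities():
    w = scale_weights(0.5, temperature=0.5)
    assert w[0] / w[1] == pytest.approx(1.0)
    assert w[2] / w[1] == pytest.approx(np.exp(-4.0))


def test_scale_weights_requires_positive_temperature():
    with pytest.raises(ValueError):
        scale_weights(1.0, temperature=0.0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.floats(-3, 5), st.floats(0.05, 3))
def test_scale_weights_always_on_simplex(s, temp):
    w = scale_weights(s, temp)
    assert np.all(w >= 0)
    assert w.sum() == pytest.approx(1.0)


# -- attention masks ---------------------------------------------------------

def test_mask_peak_equals_scale_weight_at_fixation_pixel():
    fx = Fixation(location=np.array([16.0, 8.0]), scale_weights=scale_weights(1.0), scale=1.0)
    masks = attention_masks(fx, image_size=64)
    for lvl in range(3):
        x, y = (fx.location / 2**lvl).astype(int)
        assert masks.masks[lvl][y, x] == pytest.approx(fx.scale_weights[lvl])


def test_mask_falls_to_exp_minus_half_at_one_sd():
    fx = Fixation(location=np.array([32.0, 32.0]), scale_weights=np.array([1.0, 0.0, 0.0]))
    masks = attention_masks(fx, image_size=64)
    peak = masks.masks[0][32, 32]
    # full-resolution SD is half the 8-px window = 4 px
    assert masks.masks[0][32, 36] / peak == pytest.approx(np.exp(-0.5))


def test_apply_masks_identity_zero_and_spot_products():
    rng = np.random.default_rng(0)
    pyr = build_pyramid(rng.uniform(size=(16, 16)))
    ones = AttentionMaskSet(masks=tuple(np.ones_like(lv) for lv in pyr.levels))
    for lv, out in zip(pyr.levels, apply_masks(pyr, ones)):
        assert np.array_equal(out, lv)
    zeros = AttentionMaskSet(masks=tuple(np.zeros_like(lv) for lv in pyr.levels))
    assert all(np.all(out == 0) for out in apply_masks(pyr, zeros))
    rand = AttentionMaskSet(masks=tuple(rng.uniform(size=lv.shape) for lv in pyr.levels))
    out = apply_masks(pyr, rand)
    for lvl in range(3):
        for _ in range(10):
            i, j = rng.integers(0, pyr.levels[lvl].shape[0], 2)
            assert out[lvl][i, j] == pyr.levels[lvl][i, j] * rand.masks[lvl][i, j]
    bad = AttentionMaskSet(masks=(np.ones((3, 3)),) * 3)
    with pytest.raises(ValueError):
        apply_masks(pyr, bad)


# -- centre bias -------------------------------------------------------------

def test_center_bias_zero_at_centre_and_two_at_corner():
    centre = GazeStrategy(
        rois=[ROI(np.array([32.0, 32.0, 1.0]), np.eye(3))] * 3, image_size=64
    )
    assert center_bias_penalty(centre) == pytest.approx(0.0)
    corner = GazeStrategy(
        rois=[
            ROI(np.array([0.0, 0.0, 1.0]), np.eye(3)),
            ROI(np.array([32.0, 32.0, 1.0]), np.eye(3)),
            ROI(np.array([32.0, 32.0, 1.0]), np.eye(3)),
        ],
        image_size=64,
    )
    assert center_bias_penalty(corner) == pytest.approx(2.0)


def test_center_bias_monotone_in_distance():
    vals = []
    for off in (0.0, 4.0, 8.0, 16.0):
        s = GazeStrategy(
            rois=[ROI(np.array([32.0 + off, 32.0, 1.0]), np.eye(3))] * 3, image_size=64
        )
        vals.append(center_bias_penalty(s))
    assert np.all(np.diff(vals) > 0)


# -- sampling ----------------------------------------------------------------

def test_degenerate_sampling_hits_roi_means_exactly():
    strat = _reference_strategy(spatial_sd=1.0, saccade=0.0)
    for roi in strat.rois:
        roi.covariance = np.eye(3) * 1e-18
    seq = sample_fixation_sequence(strat, np.random.default_rng(0))
    for fx, roi in zip(seq.fixations, strat.rois):
        assert np.allclose(fx.location, roi.mean[:2], atol=1e-6)


def test_sampled_moments_match_emission_plus_saccade_convolution():
    strat = _reference_strategy(spatial_sd=4.0, saccade=3.0)
    rng = np.random.default_rng(7)
    first = np.array(
        [sample_fixation_sequence(strat, rng, clip_to_image=False).fixations[0].location
         for _ in range(10_000)]
    )
    expect_cov = strat.rois[0].covariance[:2, :2] + 9.0 * np.eye(2)
    se = np.sqrt(np.diag(expect_cov) / 10_000)
    assert np.all(np.abs(first.mean(axis=0) - strat.rois[0].mean[:2]) < 3 * se)
    assert np.allclose(np.cov(first.T), expect_cov, rtol=0.1, atol=1.0)


def test_deterministic_chain_visits_rois_in_order():
    strat = _reference_strategy(spatial_sd=0.1, saccade=0.0)
    assert np.array_equal(strat.prior, [1, 0, 0])
    assert np.array_equal(strat.transition, [[0, 1, 0], [0, 0, 1], [0, 0, 1]])
    rng = np.random.default_rng(1)
    for _ in range(5):
        seq = sample_fixation_sequence(strat, rng)
        for fx, roi in zip(seq.fixations, strat.rois):
            assert np.linalg.norm(fx.location - roi.mean[:2]) < 2.0


def test_invalid_models_are_rejected():
    with pytest.raises(ValueError):
        ROI(np.zeros(3), np.diag([1.0, -1.0, 1.0]))  # not positive definite
    with pytest.raises(ValueError):
        GazeStrategy(
            rois=[ROI(np.zeros(3), np.eye(3))] * 2,
            prior=np.array([0.6, 0.6]),
            transition=np.eye(2),
        )


def test_strategy_json_roundtrip(tmp_path):
    strat = _reference_strategy()
    strat.to_json(tmp_path / "s.json")
    back = GazeStrategy.from_json(tmp_path / "s.json")
    for a, b in zip(strat.rois, back.rois):
        assert np.allclose(a.mean, b.mean)
        assert np.allclose(a.covariance, b.covariance)
    assert back.saccade_noise_sd == strat.saccade_noise_sd


def test_effective_hmm_adds_saccade_noise_to_spatial_variances():
    strat = _reference_strategy(spatial_sd=4.0, saccade=3.0)
    eff = strat.effective_hmm(include_scale=True)
    assert eff["covariances"][0][0, 0] == pytest.approx(16.0 + 9.0)
    assert eff["covariances"][0][2, 2] == pytest.approx(0.25)  # scale untouched
    eff2d = strat.effective_hmm(include_scale=False)
    assert eff2d["means"].shape == (3, 2)


# -- differentiability -------------------------------------------------------

@pytest.mark.usefixtures("float64_graph")
def test_mask_is_differentiable_wrt_location_and_scale():
    def loss_loc(loc):
        w = ad.Tensor(np.array([[0.7]]))
        return (attention_mask_tensor(loc, w, level=0, image_size=16) ** 2).sum()

    assert gradcheck(loss_loc, np.array([[5.0, 7.0]]), eps=1e-5) < 1e-5

    def loss_scale(s):
        w = scale_weights_tensor(s)
        return (w * ad.Tensor(np.array([[0.3, 0.5, 0.2]]))).sum() ** 2

    assert gradcheck(loss_scale, np.array([[0.8]]), eps=1e-5) < 1e-6
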