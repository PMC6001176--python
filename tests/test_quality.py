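"""Unit and property tests for the six-step blur-assessment pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from dogblur.quality import (
    DoGParams,
    EmptyForegroundError,
    FeatureTrajectory,
    MultiscaleConfig,
    assess_image,
    dog_kernel,
    dog_response,
    extract_foreground,
    gaussian_kernel,
    local_contrast_map,
    masked_mean,
    multiscale_trajectory,
    predict_quality,
    rescale_to_reference_range,
    scale_range,
)
from dogblur.simulate import apply_gaussian_blur

from oracles import dense_convolve_symmetric, loop_local_contrast, loop_masked_mean


# ---------------------------------------------------------------------------
# Step 1: rescaling
# ---------------------------------------------------------------------------

class TestRescale:
    def test_linear_map_of_endpoints(self):
        img = np.linspace(0.0, 4.0, 256).reshape(16, 16)
        img[0, 0], img[0, 1], img[1, 0], img[1, 1] = 0, 1, 2, 4
        img[-1, -1] = 4.0
        img[0, 0] = 0.0
        out = rescale_to_reference_range(img)
        assert out.min() == 0.0 and out.max() == 255.0
        np.testing.assert_allclose(
            out[:2, :2], [[0.0, 63.75], [127.5, 255.0]], atol=1e-12
        )

    def test_identity_when_already_full_range(self):
        img = np.zeros((16, 16))
        img[0, 0] = 255.0
        img[3, 4] = 100.0
        np.testing.assert_array_equal(rescale_to_reference_range(img), img)

    def test_constant_image_maps_to_zero(self):
        out = rescale_to_reference_range(np.full((20, 20), 5.0))
        assert np.all(out == 0.0)

    @pytest.mark.parametrize(
        "bad",
        [
            np.full((8, 8), 1.0),  # too small
            np.full((16, 15), 1.0),  # one dim too small
        ],
    )
    def test_too_small_rejected(self, bad):
        with pytest.raises(ValueError):
            rescale_to_reference_range(bad)

    def test_non_finite_rejected(self):
        img = np.ones((16, 16))
        img[4, 4] = np.nan
        with pytest.raises(ValueError):
            rescale_to_reference_range(img)


# ---------------------------------------------------------------------------
# Step 2: foreground
# ---------------------------------------------------------------------------

class TestForeground:
    def test_bright_block_is_exactly_the_mask(self):
        img = np.zeros((32, 32))
        img[10:22, 10:22] = 200.0
        assert img.mean() < 200.0
        mask = extract_foreground(img, min_component_area=0)
        expected = np.zeros((32, 32), dtype=bool)
        expected[10:22, 10:22] = True
        np.testing.assert_array_equal(mask, expected)
        assert mask.sum() == 144

    def test_annulus_hole_is_filled(self):
        img = np.zeros((40, 40))
        yy, xx = np.mgrid[0:40, 0:40]
        r = np.hypot(yy - 19.5, xx - 19.5)
        img[(r >= 8) & (r <= 14)] = 255.0
        mask = extract_foreground(img, min_component_area=0)
        assert mask[20, 20]  # center of the hole
        assert not mask[0, 0]

    def test_small_component_removed(self):
        img = np.zeros((64, 64))
        img[2:32, 2:32] = 200.0  # 900 px
        img[50:60, 50:55] = 200.0  # 50 px
        mask = extract_foreground(img, min_component_area=800)
        assert mask[10, 10]
        assert not mask[52, 52]
        assert mask.sum() == 900

    def test_empty_after_cleaning_raises(self):
        img = np.zeros((32, 32))
        img[2:6, 2:6] = 200.0  # 16 px, below any sane area threshold
        with pytest.raises(EmptyForegroundError):
            extract_foreground(img, min_component_area=800)


# ---------------------------------------------------------------------------
# Step 3: masked mean
# ---------------------------------------------------------------------------

class TestMaskedMean:
    def test_full_and_partial_masks(self):
        img = np.array([[10.0, 20.0], [30.0, 40.0]])
        assert masked_mean(img, np.ones((2, 2), bool)) == 25.0
        first_row = np.array([[True, True], [False, False]])
        assert masked_mean(img, first_row) == 15.0

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyForegroundError):
            masked_mean(np.ones((4, 4)), np.zeros((4, 4), bool))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            masked_mean(np.ones((4, 4)), np.ones((4, 5), bool))

    def test_matches_index_loop_oracle(self, rng):
        for _ in range(100):
            img = rng.normal(size=(16, 16)) * 50
            mask = rng.random((16, 16)) > 0.4
            if not mask.any():
                mask[0, 0] = True
            assert masked_mean(img, mask) == pytest.approx(
                loop_masked_mean(img, mask), abs=1e-9
            )


# ---------------------------------------------------------------------------
# Step 4: kernels, scale range, convolution
# ---------------------------------------------------------------------------

class TestKernels:
    @pytest.mark.parametrize("sigma", [0.5, 1.0, 2.0, 3.7])
    def test_gaussian_unit_sum_symmetry_support(self, sigma):
        k = gaussian_kernel(sigma)
        side = 2 * int(np.ceil(3 * sigma)) + 1
        assert k.shape == (side, side)
        assert abs(k.sum() - 1.0) < 1e-12
        np.testing.assert_array_equal(k, k[::-1, :])
        np.testing.assert_array_equal(k, k[:, ::-1])
        np.testing.assert_array_equal(k, k.T)

    def test_gaussian_matches_pointwise_formula(self):
        sigma = 1.0
        k = gaussian_kernel(sigma)
        r = k.shape[0] // 2
        x = np.arange(-r, r + 1)
        xx, yy = np.meshgrid(x, x, indexing="ij")
        direct = np.exp(-(xx**2 + yy**2) / (2 * sigma**2))
        direct /= direct.sum()
        np.testing.assert_allclose(k, direct, atol=1e-14)
        assert k[r, r] == k.max()
        center_row = k[r, r:]
        assert np.all(np.diff(center_row) < 0)  # monotone radial decay

    def test_gaussian_invalid_sigma(self):
        with pytest.raises(ValueError):
            gaussian_kernel(0.0)

    def test_dog_zero_sum_and_degenerate(self):
        for params in [DoGParams(1, 2), DoGParams(2, 3), DoGParams(1.5, 4)]:
            assert abs(dog_kernel(params).sum()) < 1e-10
        assert np.all(dog_kernel(DoGParams(2, 2)) == 0.0)

    def test_schedules_coincide_at_first_scale(self):
        cfg = MultiscaleConfig()
        theta1 = cfg.high_energy_schedule(5)[0]
        theta2 = cfg.low_energy_schedule(5)[0]
        assert theta1 == theta2 == DoGParams(1.0, 2.0)
        np.testing.assert_array_equal(dog_kernel(theta1), dog_kernel(theta2))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DoGParams(2, 1).validate()

    def test_response_matches_dense_double_loop(self, rng):
        img = rng.random((16, 16)) * 255
        for params in [DoGParams(1, 2), DoGParams(2, 3)]:
            expected = dense_convolve_symmetric(img, dog_kernel(params))
            np.testing.assert_allclose(dog_response(img, params), expected, atol=1e-9)


class TestScaleRange:
    @pytest.mark.parametrize(
        "d1,d2,expected", [(256, 256, 11), (512, 512, 16), (448, 390, 14), (16, 16, 2)]
    )
    def test_examples(self, d1, d2, expected):
        assert scale_range(d1, d2) == expected

    def test_small_dims_rejected(self):
        with pytest.raises(ValueError):
            scale_range(8, 256)


# ---------------------------------------------------------------------------
# Step 5: local contrast
# ---------------------------------------------------------------------------

class TestLocalContrast:
    def test_constant_response_gives_zero_map(self):
        out = local_contrast_map(np.full((20, 20), 3.0), window=5)
        assert out.shape == (20, 20)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_step_edge_support_and_values(self):
        img = np.zeros((16, 16))
        img[:, 8:] = 100.0
        out = local_contrast_map(img, window=5, operator="std")
        assert np.all(out[:, :6] == 0.0) and np.all(out[:, 10:] == 0.0)
        assert np.all(out[:, 6:10] > 0.0)
        np.testing.assert_allclose(out, loop_local_contrast(img, 5, "std"), atol=1e-9)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            local_contrast_map(np.zeros((8, 8)), window=4)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        arr=hnp.arrays(
            np.float64,
            (16, 16),
            elements=st.floats(-100, 100, allow_nan=False, width=32),
        ),
        operator=st.sampled_from(["std", "range"]),
    )
    def test_matches_window_loop_oracle(self, arr, operator):
        out = local_contrast_map(arr, window=5, operator=operator)
        assert np.all(out >= 0.0)
        # 1e-6 is the conditioning bound of the sliding-variance identity
        # at intensity scale ~100 on adversarial near-constant windows;
        # random inputs agree to ~1e-12
        np.testing.assert_allclose(
            out, loop_local_contrast(arr, 5, operator), atol=1e-6
        )


# ---------------------------------------------------------------------------
# Step 4+5 composed: the trajectory
# ---------------------------------------------------------------------------

class TestTrajectory:
    def test_first_scale_identity_and_length(self, brain_phantom):
        rescaled = rescale_to_reference_range(brain_phantom)
        mask = extract_foreground(rescaled)
        traj = multiscale_trajectory(rescaled, mask)
        L = scale_range(*brain_phantom.shape)
        assert traj.L == L == len(traj.mu_high) == len(traj.mu_low)
        assert traj.mu_high[0] == pytest.approx(traj.mu_low[0], abs=1e-10)

    def test_final_ordering_on_phantom(self, brain_phantom, cardiac_phantom):
        for img in (brain_phantom, cardiac_phantom):
            rescaled = rescale_to_reference_range(img)
            mask = extract_foreground(rescaled)
            traj = multiscale_trajectory(rescaled, mask)
            assert traj.mu_cb <= traj.mu_ca + 1e-9
            assert traj.distance >= 0.0

    def test_invalid_L_rejected(self, brain_phantom):
        rescaled = rescale_to_reference_range(brain_phantom)
        mask = extract_foreground(rescaled)
        with pytest.raises(ValueError):
            multiscale_trajectory(rescaled, mask, L=1)


# ---------------------------------------------------------------------------
# Step 6: quality index
# ---------------------------------------------------------------------------

class TestPredictQuality:
    def test_worked_example(self):
        score = predict_quality((30.0, 6.0, 40.0))
        assert score.q1 == pytest.approx(0.6, abs=1e-12)
        assert score.q2 == pytest.approx(24.0 / 46.0, abs=1e-12)
        assert score.Q == pytest.approx((0.6 + 24.0 / 46.0) / 2.0, abs=1e-12)

    def test_degraded_limit_zero_distance(self):
        score = predict_quality((12.0, 12.0, 40.0))
        assert (score.q1, score.q2, score.Q) == (0.0, 0.0, 0.0)

    def test_ideal_limit(self):
        score = predict_quality((40.0, 0.0, 40.0))
        assert (score.q1, score.q2, score.Q) == (1.0, 1.0, 1.0)

    def test_zero_reference_scores_zero(self):
        warnings: list = []
        score = predict_quality((0.0, 0.0, 0.0), warnings=warnings)
        assert (score.q1, score.q2, score.Q) == (0.0, 0.0, 0.0)
        assert warnings

    def test_clamping_and_warning_capture(self):
        warnings: list = []
        score = predict_quality((100.0, 0.0, 40.0), warnings=warnings)
        assert score.q1 == 1.0 and score.Q == 1.0
        assert any("clamp" in w for w in warnings)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        mu_ca=st.floats(0, 300),
        mu_cb=st.floats(0, 300),
        mu_id=st.floats(0.01, 300),
    )
    def test_bounds_mean_identity_and_score_ordering(self, mu_ca, mu_cb, mu_id):
        s = predict_quality((mu_ca, mu_cb, mu_id))
        assert 0.0 <= s.q1 <= 1.0 and 0.0 <= s.q2 <= 1.0 and 0.0 <= s.Q <= 1.0
        assert s.Q == (s.q1 + s.q2) / 2.0
        assert s.q2 <= s.q1 + 1e-12  # larger denominator


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

class TestAssessImage:
    def test_constant_image_scores_zero(self):
        res = assess_image(np.full((64, 64), 9.0))
        assert (res.score.q1, res.score.q2, res.score.Q) == (0.0, 0.0, 0.0)

    def test_deterministic_bit_identical(self, brain_phantom):
        a = assess_image(brain_phantom)
        b = assess_image(brain_phantom)
        assert a.score == b.score
        assert a.trajectory == b.trajectory
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_blur_strictly_lowers_quality(self, brain_phantom, cardiac_phantom):
        for img in (brain_phantom, cardiac_phantom):
            sharp = assess_image(img).score.Q
            blurred = assess_image(apply_gaussian_blur(img, 15)).score.Q
            assert sharp > blurred

    def test_quality_decreases_toward_limit_under_extreme_preblur(self, brain_phantom):
        from scipy.ndimage import gaussian_filter

        q_mild = assess_image(apply_gaussian_blur(brain_phantom, 15)).score.Q
        q_extreme = assess_image(gaussian_filter(brain_phantom, 12.0)).score.Q
        assert q_extreme < q_mild

    def test_foreground_retry_warns_on_small_grid(self):
        img = np.zeros((20, 20))
        img[5:15, 5:15] = 200.0  # 100 px < default 800 -> retry path
        res = assess_image(img)
        assert any("min_component_area" in w for w in res.warnings)
        assert 0.0 <= res.score.Q <= 1.0
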