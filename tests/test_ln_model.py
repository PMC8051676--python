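import numpy as np
import pytest

from rgcspatial.core_data import TrialResponseTable
from rgcspatial.ln_model import (
    cc_norm,
    clip_to_rf,
    crossvalidate_ln,
    fit_bilogistic,
    fit_single_logistic,
    linear_prediction,
    logistic,
    preprocess_image,
    signal_power,
)
from rgcspatial.synthetic import simulate_flash_counts

from .conftest import small_rf


class TestPreprocess:
    def test_sd_normalized_to_forty_percent(self):
        rng = np.random.default_rng(0)
        raw = 100.0 + 120.0 * rng.standard_normal((64, 64))  # SD 3x target
        out = preprocess_image(raw, background=100.0, quantize=False)
        # pre-clip the affine map gives SD 0.4 exactly; clipping at +-1
        # trims the ~1.2% of mass beyond 2.5 sigma only slightly
        assert out.std() == pytest.approx(0.4, abs=0.01)
        assert out.mean() == pytest.approx(0.0, abs=0.01)

    def test_binary_image_maps_to_symmetric_contrast(self):
        # a symmetric binary image lands at +-0.4: the normalization pins
        # the SD to 40% of the mean, so clipping never engages here
        raw = np.zeros((8, 8))
        raw[::2] = 200.0  # {0, 2*background}
        out = preprocess_image(raw, background=100.0, quantize=False)
        assert np.allclose(sorted(np.unique(out)), [-0.4, 0.4])

    def test_quantization_levels(self):
        rng = np.random.default_rng(1)
        raw = 100 + 40 * rng.standard_normal((32, 32))
        out = preprocess_image(raw, background=100.0)
        levels = np.unique(np.round((out + 1) / 2 * 255, 6))
        assert np.allclose(levels, np.round(levels))

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            preprocess_image(np.full((4, 4), 7.0), 7.0)


class TestClipToRf:
    def test_crop_covers_four_sigma(self, images_small):
        rf = small_rf(60.0)
        s, k, _ = clip_to_rf(images_small[0], rf)
        side = int(np.sqrt(k.size))
        assert side >= 480.0 / 7.5  # 4 sigma radius = 240 um, box 480 um

    def test_filter_nonnegative_and_normalized(self, images_small):
        rf = small_rf(60.0)  # surround-free
        _, k, _ = clip_to_rf(images_small[0], rf)
        assert np.all(k >= 0)
        assert np.abs(k).sum() == pytest.approx(1.0)

    def test_filter_independent_of_image(self, images_small):
        rf = small_rf(60.0)
        _, k1, _ = clip_to_rf(images_small[0], rf)
        _, k2, _ = clip_to_rf(2.0 * images_small[0], rf)
        assert np.array_equal(k1, k2)


class TestLinearPrediction:
    def test_homogeneous_image(self):
        k = np.full(16, 1.0 / 16)
        s = np.full(16, 0.37)
        assert linear_prediction(k, s) == pytest.approx(0.37)

    def test_orthogonal(self):
        k = np.array([0.5, 0.5, 0.0])
        s = np.array([1.0, -1.0, 3.0])
        assert linear_prediction(k, s) == pytest.approx(0.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            k = rng.normal(size=50)
            s = rng.normal(size=50)
            brute = sum(float(a) * float(b) for a, b in zip(k, s))
            assert linear_prediction(k, s) == pytest.approx(brute)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            linear_prediction(np.ones(3), np.ones(4))


class TestBilogistic:
    def test_monotone_logistic_recovered(self):
        rng = np.random.default_rng(3)
        g = rng.uniform(-0.5, 0.5, 200)
        y = logistic(g, 0.5, 8.0, 10.0, 0.1)
        fit = fit_bilogistic(g, y)
        grid = np.linspace(-0.5, 0.5, 200)
        rms = np.sqrt(np.mean((fit(grid) - logistic(grid, 0.5, 8.0, 10.0, 0.1)) ** 2))
        assert rms < 0.01 * y.max()

    def test_u_shaped_recovered(self):
        rng = np.random.default_rng(4)
        g = rng.uniform(-0.6, 0.6, 300)
        y = 0.3 + 6.0 / (1 + np.exp(-12 * (g - 0.2))) + 4.0 / (1 + np.exp(12 * (g + 0.2)))
        fit = fit_bilogistic(g, y)
        # both lobes present; minimum near g = 0
        assert fit(0.6) > fit(0.0) + 2.0
        assert fit(-0.6) > fit(0.0) + 1.0
        assert abs(fit(0.0) - y.min()) < 1.0

    def test_constant_data(self):
        rng = np.random.default_rng(5)
        g = rng.uniform(-1, 1, 50)
        y = np.full(50, 3.0)
        fit = fit_bilogistic(g, y)
        assert np.allclose(fit(np.linspace(-1, 1, 20)), 3.0, atol=0.05)

    def test_bilogistic_no_worse_than_single(self):
        rng = np.random.default_rng(6)
        g = rng.uniform(-0.5, 0.5, 150)
        y = logistic(g, 0.2, 5.0, -8.0, 0.0) + rng.normal(0, 0.2, 150)
        b, m, r, g0 = fit_single_logistic(g, y)
        mse_single = np.mean((logistic(g, b, m, r, g0) - y) ** 2)
        fit = fit_bilogistic(g, y)
        mse_bi = np.mean((fit(g) - y) ** 2)
        assert mse_bi <= mse_single * 1.001

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_bilogistic(np.linspace(0, 1, 10), np.ones(10))


class TestSignalPower:
    def test_noiseless_trials(self):
        y = np.array([1.0, 4.0, 2.0, 7.0, 3.0])
        counts = np.tile(y[:, None], (1, 4))
        # identical trials: [N^2 Var(y) - N Var(y)] / (N(N-1)) = Var(y)
        assert signal_power(counts) == pytest.approx(np.var(y))

    def test_pure_noise_near_zero(self):
        rng = np.random.default_rng(7)
        vals = [signal_power(rng.normal(size=(30, 5))) for _ in range(1000)]
        assert abs(np.mean(vals)) < 0.01

    def test_toy_table_matches_hand_evaluation(self):
        counts = np.array([[1.0, 3.0], [2.0, 2.0], [5.0, 1.0]])
        n = 2
        var_sum = np.var(counts.sum(axis=1))
        sum_var = np.var(counts[:, 0]) + np.var(counts[:, 1])
        expected = (var_sum - sum_var) / (n * (n - 1))
        assert signal_power(counts) == pytest.approx(expected)

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            signal_power(np.ones((5, 1)))


class TestCcNorm:
    def test_perfect_model_matches_direct_formula(self):
        y = np.array([1.0, 4.0, 2.0, 7.0, 3.0, 6.0])
        counts = np.tile(y[:, None], (1, 10))
        sp = signal_power(counts)
        expected = np.mean((y - y.mean()) ** 2) / np.sqrt(np.var(y) * sp)
        assert cc_norm(y, counts) == pytest.approx(expected)
        # noiseless data: SP = Var(y), so a perfect model scores exactly 1
        assert expected == pytest.approx(1.0)

    def test_uncorrelated_prediction_near_zero(self):
        rng = np.random.default_rng(8)
        y = rng.uniform(1, 10, 500)
        counts = y[:, None] + rng.normal(0, 0.5, (500, 8))
        y_hat = rng.uniform(1, 10, 500)
        assert abs(cc_norm(y_hat, counts)) < 0.15

    def test_affine_invariance_machine_precision(self):
        rng = np.random.default_rng(9)
        y = rng.uniform(0, 5, 100)
        counts = y[:, None] + rng.normal(0, 0.3, (100, 6))
        y_hat = rng.uniform(0, 5, 100)
        a = cc_norm(y_hat, counts)
        b = cc_norm(3.7 * y_hat + 11.0, counts)
        assert a == pytest.approx(b, rel=1e-12)

    def test_nonpositive_sp_undefined(self):
        counts = np.array([[1.0, 5.0], [5.0, 1.0], [1.0, 5.0]])
        assert np.isnan(cc_norm(np.array([1.0, 2.0, 3.0]), counts))


class TestCrossvalidation:
    def test_linear_cell_high_ccnorm(self, linear_cell, images_small):
        tab = simulate_flash_counts(linear_cell, images_small, 10, seed=1)
        fit = crossvalidate_ln(tab, images_small, linear_cell.rf, seed=0)
        assert fit.cc_norm > 0.9

    def test_rectified_cell_materially_lower(
        self, linear_cell, rectified_cell, images_small
    ):
        tab_l = simulate_flash_counts(linear_cell, images_small, 10, seed=1)
        tab_r = simulate_flash_counts(rectified_cell, images_small, 10, seed=1)
        cc_l = crossvalidate_ln(tab_l, images_small, linear_cell.rf, seed=0).cc_norm
        cc_r = crossvalidate_ln(tab_r, images_small, rectified_cell.rf, seed=0).cc_norm
        assert cc_r < cc_l - 0.02

    def test_shuffled_labels_near_zero(self, linear_cell, images_small):
        rng = np.random.default_rng(10)
        tab = simulate_flash_counts(linear_cell, images_small, 10, seed=1)
        shuffled = TrialResponseTable(
            tab.stimulus_ids, tab.counts[rng.permutation(len(images_small))], tab.window
        )
        fit = crossvalidate_ln(shuffled, images_small, linear_cell.rf, seed=0)
        assert abs(fit.cc_norm) < 0.25

    def test_filter_is_l1_normalized(self, linear_cell, images_small):
        tab = simulate_flash_counts(linear_cell, images_small, 10, seed=1)
        fit = crossvalidate_ln(tab, images_small, linear_cell.rf, seed=0)
        assert np.abs(fit.spatial_filter).sum() == pytest.approx(1.0)
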