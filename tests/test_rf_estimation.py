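import numpy as np
import pytest

from rgcspatial.rf_estimation import (
    ParametricRF,
    Sta,
    compute_sta,
    eval_spatial_dog,
    eval_temporal_filter,
    fit_parametric_rf,
    rf_center_diameter,
)


def make_rf(**kw):
    base = dict(
        center_mean=np.array([480.0, 480.0]),
        center_cov=np.diag([100.0**2, 100.0**2]),
        surround_strength=0.3,
        surround_scale=2.0,
        p1=1.0,
        p2=0.6,
        tau1=0.05,
        tau2=0.12,
        n=6.0,
    )
    base.update(kw)
    return ParametricRF(**base)


def synth_sta(rf, nx=16, ny=16, n_lags=15, stixel=60.0, frame_rate=30.0):
    xs = (np.arange(nx) + 0.5) * stixel
    ys = (np.arange(ny) + 0.5) * stixel
    xx, yy = np.meshgrid(xs, ys)
    ks = eval_spatial_dog(rf, np.stack([xx, yy], axis=-1))
    t = (np.arange(n_lags) + 0.5) / frame_rate
    kt = eval_temporal_filter(rf, t)
    return Sta(kt[:, None, None] * ks[None], stixel, frame_rate, n_spikes=10000)


class TestSpatialDog:
    def test_pure_gaussian_peak(self):
        rf = make_rf(surround_strength=0.0)
        assert eval_spatial_dog(rf, rf.center_mean) == pytest.approx(1.0)

    def test_full_cancellation(self):
        rf = make_rf(surround_strength=1.0, surround_scale=1.0)
        pts = np.array([[480.0, 480.0], [300.0, 600.0], [0.0, 0.0]])
        assert np.allclose(eval_spatial_dog(rf, pts), 0.0)

    def test_value_at_one_sigma(self):
        # mu=(0,0), Sigma=diag(100^2), A_S=0.3, kappa=2, x=(100,0):
        # independent evaluation e^(-1/2) - 0.3 e^(-1/8)
        rf = make_rf(center_mean=np.zeros(2), surround_strength=0.3)
        expected = np.exp(-0.5) - 0.3 * np.exp(-1.0 / 8.0)
        assert eval_spatial_dog(rf, np.array([100.0, 0.0])) == pytest.approx(expected)

    def test_center_value_is_one_minus_surround(self):
        rf = make_rf(surround_strength=0.45)
        assert eval_spatial_dog(rf, rf.center_mean) == pytest.approx(0.55)

    def test_invalid_covariance_rejected(self):
        with pytest.raises(ValueError):
            make_rf(center_cov=np.array([[1.0, 2.0], [2.0, 1.0]]))  # not PD


class TestTemporalFilter:
    def test_lobe_peaks_at_tau_with_value_p(self):
        rf = make_rf(p1=1.7, p2=0.0)
        assert eval_temporal_filter(rf, rf.tau1) == pytest.approx(1.7)

    def test_equal_lobes_cancel(self):
        rf = make_rf(p1=0.8, p2=0.8, tau1=0.07, tau2=0.07)
        t = np.linspace(0.01, 0.4, 50)
        assert np.allclose(eval_temporal_filter(rf, t), 0.0)

    def test_independent_evaluation(self):
        rf = make_rf(p1=1.0, p2=0.5, tau1=0.05, tau2=0.12, n=6.0)
        t = 0.08
        lobe = lambda tau: ((t / tau) * np.exp(-t / tau + 1.0)) ** 6.0
        assert eval_temporal_filter(rf, t) == pytest.approx(lobe(0.05) - 0.5 * lobe(0.12))

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            eval_temporal_filter(make_rf(), 0.0)


class TestCenterDiameter:
    def test_isotropic_is_four_sigma(self):
        rf = make_rf(center_cov=np.diag([60.0**2, 60.0**2]))
        assert rf_center_diameter(rf) == pytest.approx(240.0)

    def test_equal_area_ellipse(self):
        rf = make_rf(center_cov=np.diag([50.0**2, 200.0**2]))
        assert rf_center_diameter(rf) == pytest.approx(400.0)

    def test_rotation_invariant(self):
        th = 0.7
        r = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        cov = np.diag([40.0**2, 90.0**2])
        rot = r @ cov @ r.T
        rot = 0.5 * (rot + rot.T)
        assert rf_center_diameter(make_rf(center_cov=rot)) == pytest.approx(
            rf_center_diameter(make_rf(center_cov=cov))
        )


class TestComputeSta:
    def test_single_spike_equals_snippet(self):
        rng = np.random.default_rng(0)
        frames = rng.choice([-1.0, 1.0], size=(40, 4, 4))
        times = np.arange(40) / 20.0
        sta = compute_sta([times[30] + 0.01], frames, times, 60.0, window=0.5)
        n_lags = sta.values.shape[0]
        for lag in range(n_lags):
            assert np.array_equal(sta.values[lag], frames[30 - lag])

    def test_independent_spikes_average_to_zero(self):
        rng = np.random.default_rng(1)
        frames = rng.choice([-1.0, 1.0], size=(6000, 6, 6))
        times = np.arange(6000) / 60.0
        spikes = np.sort(rng.uniform(times[20], times[-1], 4000))
        sta = compute_sta(spikes, frames, times, 60.0)
        assert np.abs(sta.values).max() < 5.0 / np.sqrt(4000)

    def test_linear_cell_sta_matches_filter(self):
        from rgcspatial.synthetic import simulate_white_noise_spikes

        rf = make_rf(
            center_mean=np.array([480.0, 480.0]),
            surround_strength=0.2,
        )
        sta_true = synth_sta(rf)
        ks = sta_true.values[np.argmax(np.abs(sta_true.values).max(axis=(1, 2)))]
        kt = sta_true.values[:, 8, 8]
        kt = kt / np.abs(kt).max()
        ks = ks / np.abs(ks).max()
        frames, times, spikes = simulate_white_noise_spikes(
            ks, kt, n_frames=100000, frame_rate=30.0, gain=30.0, seed=5
        )
        sta = compute_sta(spikes, frames, times, 60.0)
        est = sta.values - sta.values.mean()
        tru = sta_true.values
        cos = np.sum(est * tru) / np.sqrt(np.sum(est**2) * np.sum(tru**2))
        assert cos > 0.95

    def test_few_spikes_warn(self):
        rng = np.random.default_rng(2)
        frames = rng.choice([-1.0, 1.0], size=(100, 4, 4))
        times = np.arange(100) / 30.0
        with pytest.warns(UserWarning):
            compute_sta([2.0], frames, times, 60.0)


class TestParametricFit:
    def test_noiseless_recovery(self):
        rf = make_rf()
        fit = fit_parametric_rf(synth_sta(rf))
        assert np.allclose(fit.center_mean, rf.center_mean, rtol=0.01)
        cov_err = np.linalg.norm(fit.center_cov - rf.center_cov)
        assert cov_err / np.linalg.norm(rf.center_cov) < 0.01
        assert fit.surround_strength == pytest.approx(rf.surround_strength, rel=0.01, abs=0.01)
        assert fit.tau1 == pytest.approx(rf.tau1, rel=0.01)
        assert fit.tau2 == pytest.approx(rf.tau2, rel=0.01)

    def test_noisy_diameter_within_ten_percent(self):
        rng = np.random.default_rng(7)
        rf = make_rf()
        sta = synth_sta(rf)
        snr = 10.0
        sigma = np.abs(sta.values).max() / snr
        sta.values = sta.values + rng.normal(0, sigma, sta.values.shape)
        fit = fit_parametric_rf(sta)
        assert rf_center_diameter(fit) == pytest.approx(
            rf_center_diameter(rf), rel=0.10
        )

    def test_off_cell_sign_convention(self):
        rf = make_rf()
        sta = synth_sta(rf)
        sta.values = -sta.values  # OFF cell
        fit = fit_parametric_rf(sta)
        # spatial center peak stays positive
        assert eval_spatial_dog(fit, fit.center_mean) > 0
        # temporal filter's first lobe is negative
        t = np.linspace(0.01, 0.25, 100)
        kt = eval_temporal_filter(fit, t)
        first_extreme = kt[np.argmax(np.abs(kt))]
        assert first_extreme < 0

    def test_translation_equivariance(self):
        rf = make_rf(center_mean=np.array([420.0, 540.0]))
        fit_a = fit_parametric_rf(synth_sta(rf))
        shift = 60.0  # one stixel
        rf_b = make_rf(center_mean=rf.center_mean + shift)
        fit_b = fit_parametric_rf(synth_sta(rf_b))
        assert np.allclose(
            fit_b.center_mean - fit_a.center_mean, [shift, shift], atol=1.0
        )

    def test_fit_improves_on_initialization(self):
        rng = np.random.default_rng(8)
        rf = make_rf()
        sta = synth_sta(rf)
        sta.values = sta.values + rng.normal(0, 0.02, sta.values.shape)
        fit = fit_parametric_rf(sta)
        assert np.isfinite(fit.fit_error)

    def test_pure_noise_rejected(self):
        rng = np.random.default_rng(9)
        sta = Sta(rng.normal(0, 1.0, (15, 16, 16)), 60.0, 30.0)
        with pytest.raises(ValueError):
            fit_parametric_rf(sta)
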