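"""Time-shifted models, temporal bias, kernels, clustering, cross-correlation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from whiskenc.session import BinnedSession
from whiskenc.synth import NeuronSpec, calibrate_baseline, simulate_neuron
from whiskenc.temporal import (
    SHIFTS_MS,
    TemporalCurve,
    TemporalKernelFit,
    cluster_temporal_curves,
    fit_temporal_kernel,
    fit_time_shifted,
    kernel_preferences,
    permutation_significance,
    temporal_bias,
    xcorr_lag,
)

SHIFTS = np.asarray(SHIFTS_MS, float)


class TestTemporalBias:
    def test_symmetric_curve_zero_bias(self):
        curve = TemporalCurve(SHIFTS, np.exp(-(SHIFTS / 100.0) ** 2), "midpoint")
        bias, defined = temporal_bias(curve)
        assert defined and bias == pytest.approx(0.0, abs=1e-12)

    def test_all_future_mass_bias_one(self):
        llh = np.where(SHIFTS > 0, 1.0, 0.0)
        bias, _ = temporal_bias(TemporalCurve(SHIFTS, llh, "midpoint"))
        assert bias == pytest.approx(1.0)

    def test_flat_curve_undefined(self):
        bias, defined = temporal_bias(TemporalCurve(SHIFTS, np.zeros(13), "midpoint"))
        assert not defined and np.isnan(bias)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(-2, 2), min_size=13, max_size=13))
    def test_time_reversal_negates_bias_exactly(self, values):
        llh = np.asarray(values)
        if np.ptp(llh - llh.min()) == 0:
            return
        b1, d1 = temporal_bias(TemporalCurve(SHIFTS, llh, "midpoint"))
        b2, d2 = temporal_bias(TemporalCurve(SHIFTS, llh[::-1], "midpoint"))
        if d1:
            assert b2 == -b1

    def test_shift_set_matches_convention(self):
        assert SHIFTS_MS == (-200, -150, -100, -75, -50, -25, 0, 25, 50, 75, 100, 150, 200)


class TestTimeShifted:
    def test_planted_lag_recovered(self, binned25):
        w = np.linspace(0, 2, 20)
        spec = calibrate_baseline(
            NeuronSpec(slow_weights={"midpoint": w - w.mean()}, time_shift=-0.100, seed=51),
            binned25,
            15.0,
        )
        counts = simulate_neuron(spec, binned25)
        curve = fit_time_shifted(binned25, counts, "midpoint")
        assert abs(curve.preferred_shift - (-100)) <= 25
        bias, _ = temporal_bias(curve)
        assert bias < 0

    def test_constant_feature_identical_llh(self, binned25):
        b = BinnedSession(
            binned25.bin_width,
            {"midpoint": np.full(binned25.n_bins, 5.0)},
            binned25.spike_counts,
            binned25.bin_times,
            binned25.unit_ids,
        )
        counts = np.random.default_rng(0).poisson(0.3, binned25.n_bins)
        curve = fit_time_shifted(b, counts, "midpoint")
        assert np.ptp(curve.llh) == 0.0


class TestClustering:
    def test_planted_templates_recovered(self, rng):
        x = SHIFTS / 200.0
        templates = [np.exp(-((x + 0.5) ** 2) / 0.1), np.exp(-(x**2) / 0.1), np.exp(-((x - 0.5) ** 2) / 0.1)]
        curves, labels_true = [], []
        for i in range(60):
            k = i % 3
            noisy = templates[k] + 0.05 * rng.standard_normal(13)
            curves.append(TemporalCurve(SHIFTS, noisy, "midpoint"))
            labels_true.append(k)
        labels, temps = cluster_temporal_curves(curves, k=3, seed=0)
        agreement = np.mean(labels == np.asarray(labels_true))
        assert agreement >= 0.95
        assert temps.shape == (3, 13)

    def test_duplication_invariance(self, rng):
        curves = [
            TemporalCurve(SHIFTS, rng.standard_normal(13), "midpoint") for _ in range(9)
        ]
        l1, _ = cluster_temporal_curves(curves, k=3, seed=1)
        l2, _ = cluster_temporal_curves(curves + curves, k=3, seed=1)
        np.testing.assert_array_equal(l2[:9], l2[9:])
        np.testing.assert_array_equal(l1, l2[:9])

    def test_k1_returns_global_mean(self, rng):
        curves = [TemporalCurve(SHIFTS, rng.random(13), "midpoint") for _ in range(5)]
        labels, temps = cluster_temporal_curves(curves, k=1, seed=0)
        assert np.all(labels == 0) and temps.shape == (1, 13)

    def test_fewer_curves_than_k_rejected(self):
        with pytest.raises(ValueError):
            cluster_temporal_curves([TemporalCurve(SHIFTS, np.ones(13), "m")], k=3)


class TestXcorr:
    def test_shifted_copy_recovers_lag(self, rng):
        x = rng.standard_normal(4000)
        past_driven = np.roll(x, 2)  # rate reflects the feature 2 bins ago
        lag, peak = xcorr_lag(past_driven, x, bin_width=0.025)
        assert lag == pytest.approx(-0.050)
        assert peak > 0.9
        future_driven = np.roll(x, -2)  # rate anticipates the feature
        lag, peak = xcorr_lag(future_driven, x, bin_width=0.025)
        assert lag == pytest.approx(0.050)
        assert peak > 0.9

    def test_anticorrelated_found_via_absolute_value(self, rng):
        x = rng.standard_normal(4000)
        lag, peak = xcorr_lag(-x, x, bin_width=0.025)
        assert lag == 0.0 and peak < -0.9

    def test_independent_noise_small_peak(self, rng):
        a, b = rng.standard_normal(10000), rng.standard_normal(10000)
        _, peak = xcorr_lag(a, b, bin_width=0.025)
        assert abs(peak) < 0.1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            xcorr_lag(np.ones(100), np.arange(100.0), bin_width=0.025)


class TestKernel:
    def test_noiseless_linear_target(self, kin_session):
        from whiskenc.synth import bin_ground_truth

        b20 = bin_ground_truth(kin_session, 0.020)
        x = np.asarray(b20.features["midpoint"], float)
        counts = np.roll((x - x.mean()) / x.std(), 3)  # y_t = O(t-3): past feature drives spikes
        fit = fit_temporal_kernel(b20, counts)
        feat, t_ms, tied = kernel_preferences(fit)
        assert fit.r2 >= 0.95
        assert feat == "midpoint" and t_ms == pytest.approx(-60.0)

    def test_poisson_neuron_prefers_encoded_feature(self, kin_session):
        from whiskenc.synth import bin_ground_truth

        b20 = bin_ground_truth(kin_session, 0.020)
        w = np.linspace(0, 2, 20)
        spec = calibrate_baseline(NeuronSpec(slow_weights={"midpoint": w - w.mean()}, seed=61), b20, 15.0)
        counts = simulate_neuron(spec, b20)
        fit = fit_temporal_kernel(b20, counts)
        feat, _, _ = kernel_preferences(fit)
        assert feat == "midpoint"
        fit = permutation_significance(b20, counts, fit, n_perm=200, seed=0)
        assert fit.p_value <= 0.01
        assert len(fit.null_r2) == 200

    def test_preferences_tie_break_and_flags(self):
        coef = np.zeros((3, 21))
        coef[1, 17] = 2.0  # midpoint, lag +7 bins = +140 ms
        fit = TemporalKernelFit(
            features=("speed", "midpoint", "amplitude"),
            coef=coef,
            lags_ms=np.arange(-10, 11) * 20.0,
            alpha=1.0,
            r2=0.5,
            intercept=0.0,
            feature_scale={},
        )
        feat, t_ms, tied = kernel_preferences(fit)
        assert (feat, t_ms, tied) == ("midpoint", 140.0, False)
        coef[0, 3] = -2.0  # equal AUC on speed -> tie, L < O order
        feat, _, tied = kernel_preferences(fit)
        assert feat == "speed" and tied

    def test_zero_permutations_rejected(self, kin_session):
        from whiskenc.synth import bin_ground_truth

        b20 = bin_ground_truth(kin_session, 0.020)
        counts = np.random.default_rng(0).poisson(0.3, b20.n_bins)
        fit = fit_temporal_kernel(b20, counts)
        with pytest.raises(ValueError):
            permutation_significance(b20, counts, fit, n_perm=0)
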