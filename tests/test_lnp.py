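"""LNP encoding models: likelihood oracle, recovery, forward search."""

import numpy as np
import pytest
from scipy.optimize import check_grad
from scipy.stats import spearmanr

from whiskenc.lnp import (
    DesignMatrix,
    _objective,
    build_design_matrix,
    crossval_llh,
    event_triggered_rate,
    feature_contributions,
    fit_lnp,
    forward_search,
    llh_bits_per_spike,
    poisson_negllh,
    tuning_curve,
)
from whiskenc.session import BinnedSession
from whiskenc.synth import NeuronSpec, calibrate_baseline, simulate_neuron


def _binned_from(features, counts, bw=0.05):
    n = len(next(iter(features.values())))
    return BinnedSession(bw, features, np.atleast_2d(counts), (np.arange(n) + 0.5) * bw, ["u0"])


class TestDesignMatrix:
    def test_uniform_occupancy_column_sums(self):
        x = np.tile(np.arange(20, dtype=float), 10)  # spans [0,19], 10 each
        b = _binned_from({"speed": x}, np.zeros(200))
        dm = build_design_matrix(b, ("speed",))
        block = dm.block("speed")
        np.testing.assert_array_equal(block.sum(axis=0), 10.0)
        np.testing.assert_array_equal(block.sum(axis=1), 1.0)

    def test_max_value_in_last_bin(self):
        x = np.linspace(0, 60, 100)
        b = _binned_from({"speed": x}, np.zeros(100))
        dm = build_design_matrix(b, ("speed",))
        assert dm.indices["speed"][-1] == 19

    def test_constant_feature_rejected(self):
        b = _binned_from({"speed": np.full(50, 3.0)}, np.zeros(50))
        with pytest.raises(ValueError, match="speed"):
            build_design_matrix(b, ("speed",))


class TestFit:
    def test_flat_model_recovers_mean_count(self, rng):
        n = 2000
        counts = rng.poisson(0.5, n)
        dm = DesignMatrix(("speed",), {"speed": np.zeros(n, dtype=int)}, {"speed": np.linspace(0, 1, 21)}, n)
        fit = fit_lnp(dm, counts, 0.05, beta=0.0)
        assert abs(np.exp(fit.weights["speed"][0]) - counts.mean()) < 1e-4

    def test_analytic_gradient_matches_numerical(self, rng):
        """Central-difference oracle on random small instances."""
        for trial in range(3):
            n = 50
            idx = {f: rng.integers(0, 20, n) for f in ("speed", "midpoint")}
            dm = DesignMatrix(("speed", "midpoint"), idx, {}, n)
            counts = rng.poisson(0.8, n).astype(float)
            w = rng.normal(0, 0.3, 40)
            err = check_grad(
                lambda v: _objective(v, dm, counts, 0.05)[0],
                lambda v: _objective(v, dm, counts, 0.05)[1],
                w,
            )
            assert err < 1e-5

    def test_weight_recovery_offset_ramp(self, binned50):
        w = np.linspace(0, 2, 20)
        w -= w.mean()
        spec = calibrate_baseline(NeuronSpec(slow_weights={"midpoint": w}, seed=21), binned50, 15.0)
        counts = simulate_neuron(spec, binned50)
        dm = build_design_matrix(binned50, ("midpoint",))
        fit = fit_lnp(dm, counts, 0.05)
        rho = spearmanr(fit.weights["midpoint"], w).statistic
        assert rho >= 0.9


class TestLLH:
    def test_model_equal_to_mean_rate_is_zero_bits(self, rng):
        counts = rng.poisson(0.4, 500)
        m = counts.mean()
        assert llh_bits_per_spike(np.full(500, m), counts, m) == 0.0

    def test_bits_match_poisson_likelihood_ratio_oracle(self, rng):
        """The bits/spike score equals log2 of the Poisson likelihood ratio
        against the mean-rate model, per spike (scipy logpmf oracle); a
        doubled likelihood ratio therefore adds exactly one bit."""
        from scipy.stats import poisson as pois

        counts = rng.poisson(1.0, 400)
        m = counts.mean()
        pred = np.clip(0.5 * m + 0.7 * counts, 1e-3, None)  # arbitrary model
        log_ratio = pois.logpmf(counts, pred).sum() - pois.logpmf(counts, m).sum()
        oracle_bits = log_ratio / np.log(2.0) / counts.sum()
        assert llh_bits_per_spike(pred, counts, m) == pytest.approx(oracle_bits, abs=1e-10)
        # doubling the likelihood ratio adds exactly one bit
        nll = poisson_negllh(pred, counts)
        nll_mean = poisson_negllh(np.full(400, m), counts)
        bits = (nll_mean - nll) / np.log(2.0)
        bits2 = (nll_mean - (nll - np.log(2.0))) / np.log(2.0)
        assert bits2 - bits == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_counts_flagged(self, binned50):
        dm = build_design_matrix(binned50, ("midpoint",))
        fit = crossval_llh(dm, np.zeros(binned50.n_bins), 0.05)
        np.testing.assert_array_equal(fit.fold_llh, 0.0)
        assert fit.zero_spike_folds.all()

    def test_tuned_neuron_has_positive_cv_llh(self, binned50):
        from scipy.stats import wilcoxon

        w = np.linspace(0, 2, 20)
        spec = calibrate_baseline(NeuronSpec(slow_weights={"midpoint": w - w.mean()}, seed=22), binned50, 15.0)
        counts = simulate_neuron(spec, binned50)
        dm = build_design_matrix(binned50, ("midpoint",))
        fit = crossval_llh(dm, counts, 0.05)
        assert fit.mean_llh > 0
        assert wilcoxon(fit.fold_llh, alternative="greater").pvalue < 0.05

    def test_nesting_full_vs_single(self):
        """Regularized CV LLH of the full model is not materially below the
        best single-feature model (full-length 600-s session)."""
        from whiskenc.synth import KinematicsSpec, bin_ground_truth, generate_kinematics

        ses = generate_kinematics(KinematicsSpec(duration=600.0, seed=23))
        b = bin_ground_truth(ses, 0.050)
        w = np.linspace(0, 2, 20)
        spec = calibrate_baseline(NeuronSpec(slow_weights={"midpoint": w - w.mean()}, seed=23), b, 12.0)
        counts = simulate_neuron(spec, b)
        full = crossval_llh(build_design_matrix(b, ("speed", "midpoint", "amplitude", "frequency")), counts, 0.05)
        single = crossval_llh(build_design_matrix(b, ("midpoint",)), counts, 0.05)
        assert full.mean_llh >= single.mean_llh - 0.01


class TestForwardSearch:
    def test_pure_offset_neuron_selected(self, binned50):
        w = np.linspace(0, 2, 20)
        spec = calibrate_baseline(NeuronSpec(slow_weights={"midpoint": w - w.mean()}, seed=31), binned50, 15.0)
        sel = forward_search(binned50, simulate_neuron(spec, binned50))
        assert sel.selected == ("midpoint",)

    def test_two_feature_neuron_selected(self, binned50):
        w = np.linspace(0, 1.5, 20)
        w -= w.mean()
        spec = calibrate_baseline(
            NeuronSpec(slow_weights={"midpoint": w, "speed": w.copy()}, seed=32), binned50, 15.0
        )
        sel = forward_search(binned50, simulate_neuron(spec, binned50))
        assert set(sel.selected) == {"speed", "midpoint"}

    def test_homogeneous_poisson_unclassified(self, binned50):
        spec = calibrate_baseline(NeuronSpec(seed=33), binned50, 12.0)
        sel = forward_search(binned50, simulate_neuron(spec, binned50))
        assert sel.unclassified and sel.selected == ()

    def test_selected_llh_not_below_compared_subsets(self, binned50):
        w = np.linspace(0, 2, 20)
        spec = calibrate_baseline(NeuronSpec(slow_weights={"amplitude": w - w.mean()}, seed=34), binned50, 15.0)
        sel = forward_search(binned50, simulate_neuron(spec, binned50))
        best = sel.mean_llh(sel.selected)
        for model in sel.llh_table:
            if set(model) < set(sel.selected):
                assert best >= sel.mean_llh(model) - 1e-9


class TestContributions:
    def test_pure_offset_dominates(self, binned50):
        w = np.linspace(0, 2, 20)
        spec = calibrate_baseline(NeuronSpec(slow_weights={"midpoint": w - w.mean()}, seed=41), binned50, 15.0)
        counts = simulate_neuron(spec, binned50)
        sel = forward_search(binned50, counts)
        contrib = feature_contributions(binned50, counts, sel)
        assert not contrib.undefined
        assert contrib.values["midpoint"] >= 0.8
        assert sum(contrib.values.values()) == pytest.approx(1.0, abs=1e-9)


class TestTuningCurve:
    def test_empty_bin_is_missing_not_zero(self):
        x = np.concatenate([np.linspace(0, 8, 80), np.linspace(15, 20, 20)])
        b = _binned_from({"speed": x}, np.ones(100))
        _, mean, _ = tuning_curve(b, np.ones(100), "speed")
        assert np.isnan(mean).any()
        assert np.nanmin(mean) > 0

    def test_flat_neuron_flat_curve(self, binned50):
        spec = calibrate_baseline(NeuronSpec(seed=42), binned50, 15.0)
        counts = simulate_neuron(spec, binned50)
        _, mean, sem = tuning_curve(binned50, counts, "midpoint")
        ok = np.isfinite(mean) & np.isfinite(sem)
        within = np.abs(mean[ok] - 15.0) <= 2 * sem[ok]
        assert within.mean() >= 0.8


class TestPETH:
    def test_events_at_spikes_peak_at_zero(self, rng):
        spikes = np.sort(rng.uniform(10, 290, 400))
        lags, mean, _, _ = event_triggered_rate(spikes, spikes[::4], 300.0, window=0.5, bin_width=0.05)
        assert np.argmax(mean) == len(lags) // 2

    def test_out_of_bounds_events_dropped(self, rng):
        spikes = np.sort(rng.uniform(0, 100, 200))
        events = np.array([0.1, 0.5, 20.0, 40.0, 50.0, 60.0, 70.0, 80.0, 99.9])
        _, _, _, n_dropped = event_triggered_rate(spikes, events, 100.0, window=1.0)
        assert n_dropped == 3

    def test_random_events_flat_peth(self, rng):
        spikes = np.sort(rng.uniform(0, 300, 3000))
        events = np.sort(rng.uniform(5, 295, 100))
        lags, mean, sem, _ = event_triggered_rate(spikes, events, 300.0, window=1.0, bin_width=0.1)
        within = np.abs(mean - 10.0) <= 2.5 * sem
        assert within.mean() >= 0.8
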