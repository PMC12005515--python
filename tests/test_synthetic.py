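"""Synthetic-data generator: stated behavioral statistics and Poisson law."""

import numpy as np
import pytest

from whiskenc.synth import (
    BoutSpec,
    KinematicsSpec,
    NeuronSpec,
    PopulationSpec,
    apply_trim_effect,
    bin_ground_truth,
    calibrate_baseline,
    generate_kinematics,
    generate_population,
    simulate_neuron,
)


class TestKinematics:
    def test_degenerate_spec_pure_sinusoid(self):
        """Zero-variance processes and a fixed 19.2-Hz cycle draw produce a
        periodic angle with period 52.08 ms."""
        spec = KinematicsSpec(
            duration=20.0,
            seed=0,
            period_gamma_shape=1e9,  # vanishing period variance
            mean_period_target=1.0 / 19.2,
            noise_sd=0.0,
        )
        s = generate_kinematics(spec)
        starts = s.meta["gt_cycle_starts"]
        periods = np.diff(starts) / s.angle_rate
        np.testing.assert_allclose(periods, 1 / 19.2, atol=1.1 / s.angle_rate)

    def test_mean_period_within_10pct(self):
        s = generate_kinematics(KinematicsSpec(duration=600.0, seed=21))
        assert 0.047 <= s.meta["gt_mean_period"] <= 0.057

    def test_amplitude_and_speed_nonnegative(self, kin_session):
        assert np.all(np.asarray(kin_session.meta["gt_amplitude"]) >= 0)
        assert np.all(kin_session.speed >= 0)

    def test_coupling_half_gives_mid_correlation(self):
        rs = []
        for seed in range(4):
            spec = KinematicsSpec(duration=300.0, coupling=0.5, seed=200 + seed)
            s = generate_kinematics(spec)
            rs.append(np.corrcoef(s.speed, np.asarray(s.meta["gt_amplitude"]))[0, 1])
        assert 0.3 <= np.mean(rs) <= 0.7

    def test_invalid_coupling_rejected(self):
        with pytest.raises(ValueError, match="coupling"):
            generate_kinematics(KinematicsSpec(duration=10.0, coupling=1.5))

    def test_session_statistics_match_stated_world(self):
        """A 600-s session produces whisk-cycle and locomotion totals in the
        reported per-session ranges (5,857±1,507 cycles; 103±28 m)."""
        s = generate_kinematics(KinematicsSpec(duration=600.0, seed=77))
        gate = s.meta["gt_whisk_gate"].astype(bool)
        n_cycles = gate[np.asarray(s.meta["gt_cycle_starts"])].sum()
        meters = s.speed.mean() * 600.0 / 100.0
        assert 4350 <= n_cycles <= 7364
        assert 75 <= meters <= 131


class TestSimulateNeuron:
    def test_homogeneous_poisson_mean(self, binned50):
        n = binned50.n_bins
        spec = NeuronSpec(baseline_log_rate=np.log(0.5), seed=4)
        counts = simulate_neuron(spec, binned50)
        assert abs(counts.mean() - 0.5) < 3 * np.sqrt(0.5 / n)

    def test_poisson_dispersion(self, binned50):
        spec = NeuronSpec(baseline_log_rate=np.log(1.0), seed=5)
        counts = np.concatenate([simulate_neuron(spec, binned50, rng=np.random.default_rng(k)) for k in range(20)])
        assert 0.9 <= counts.var() / counts.mean() <= 1.1

    def test_offset_ramp_gives_monotone_tuning(self, binned50):
        from whiskenc.lnp import tuning_curve

        w = np.linspace(0, 2, 20)
        spec = calibrate_baseline(
            NeuronSpec(slow_weights={"midpoint": w - w.mean()}, seed=6), binned50, 15.0
        )
        counts = simulate_neuron(spec, binned50)
        centers, mean, _ = tuning_curve(binned50, counts, "midpoint")
        ok = np.isfinite(mean)
        rho = np.corrcoef(centers[ok], mean[ok])[0, 1]
        assert rho > 0.9

    def test_phase_peak_recovered_by_circular_mean(self, kin_session, binned50):
        from whiskenc.phase import circular_mean
        from whiskenc.synth import _von_mises_curve, counts_to_spike_times

        b5 = bin_ground_truth(kin_session, 0.005)
        spec = calibrate_baseline(
            NeuronSpec(phase_curve=_von_mises_curve(-np.pi / 2, 2.0), seed=7), b5, 20.0
        )
        counts = simulate_neuron(spec, b5)
        st = counts_to_spike_times(counts, 0.005, np.random.default_rng(8))
        gt_phase = np.asarray(kin_session.meta["gt_phase"], float)
        idx = np.clip((st * 500).astype(int), 0, len(gt_phase) - 1)
        assert len(st) >= 1000
        err = np.angle(np.exp(1j * (circular_mean(gt_phase[idx]) + np.pi / 2)))
        assert abs(err) < np.deg2rad(30)

    def test_determinism_under_fixed_seed(self, binned50):
        spec = NeuronSpec(baseline_log_rate=np.log(0.3), seed=11)
        c1 = simulate_neuron(spec, binned50)
        c2 = simulate_neuron(spec, binned50)
        np.testing.assert_array_equal(c1, c2)

    def test_rate_overflow_raises(self, binned50):
        spec = NeuronSpec(
            slow_weights={"midpoint": np.full(20, 10.0)}, baseline_log_rate=1.0
        )
        with pytest.raises(ValueError, match="overflow"):
            simulate_neuron(spec, binned50)


class TestPopulation:
    def test_bookkeeping_and_determinism(self):
        pspec = PopulationSpec(n_neurons=10, seed=5, fraction_phase_tuned=0.5)
        kspec = KinematicsSpec(duration=60.0, seed=5)
        s1, truth1, _ = generate_population(pspec, kspec)
        s2, truth2, _ = generate_population(pspec, kspec)
        assert len(truth1) == 10
        assert truth1["phase_tuned"].sum() == truth2["phase_tuned"].sum()
        for a, b in zip(s1.spikes, s2.spikes):
            np.testing.assert_array_equal(a, b)

    def test_no_phase_tuning_when_fraction_zero(self):
        pspec = PopulationSpec(n_neurons=8, seed=6, fraction_phase_tuned=0.0)
        _, truth, specs = generate_population(pspec, KinematicsSpec(duration=60.0, seed=6))
        assert not truth["phase_tuned"].any()
        assert all(sp.phase_curve is None for sp in specs)

    def test_mix_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            PopulationSpec(n_neurons=5, mix_1d=0.5, mix_multi=0.4)


class TestTrimEffect:
    def test_rate_factor_construction(self):
        pspec = PopulationSpec(
            n_neurons=8, seed=9, trim_effect={"none": 1.0}, fraction_phase_tuned=0.0
        )
        kspec = KinematicsSpec(duration=120.0, seed=9)
        pre, truth, specs = generate_population(pspec, kspec)
        post, _ = apply_trim_effect(
            pre, truth, specs, kspec_post=KinematicsSpec(duration=120.0, seed=109)
        )
        pre_rate = np.mean([len(st) for st in pre.spikes]) / pre.duration
        post_rate = np.mean([len(st) for st in post.spikes]) / post.duration
        assert abs(post_rate / pre_rate - 0.8) < 0.05

    def test_lost_unit_flattened(self):
        pspec = PopulationSpec(
            n_neurons=4, seed=10, trim_effect={"lost": 1.0}, fraction_phase_tuned=0.5
        )
        pre, truth, specs = generate_population(pspec, KinematicsSpec(duration=60.0, seed=10))
        _, post_specs = apply_trim_effect(
            pre, truth, specs, kspec_post=KinematicsSpec(duration=60.0, seed=110)
        )
        assert all(not sp.slow_weights and sp.phase_curve is None for sp in post_specs)

    def test_unknown_label_rejected(self):
        pspec = PopulationSpec(n_neurons=2, seed=11, trim_effect={"none": 1.0})
        pre, truth, specs = generate_population(pspec, KinematicsSpec(duration=60.0, seed=11))
        truth.loc[0, "trim_label"] = "exploded"
        with pytest.raises(ValueError, match="unknown trim label"):
            apply_trim_effect(pre, truth, specs, kspec_post=KinematicsSpec(duration=60.0, seed=111))
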