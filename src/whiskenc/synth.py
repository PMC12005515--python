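"""Synthetic whisking/locomotion kinematics and Poisson spiking populations.

The generator states a behavioral world matching what is known about
head-fixed mice whisking in air on a treadmill: rhythmic whisking in the
5–25 Hz band with a mean cycle period near 52 ms, slowly drifting midpoint
and amplitude envelopes, bout-structured locomotion over a wide speed range,
and a positive coupling between locomotion speed and the whisking envelopes.
Angle is built constructively as

    θ(t) = midpoint(t) − amplitude(t) · (1 − cos φ(t))

so that the midpoint is the protracted (upper) envelope bound and the
decomposition has an exact ground truth, stored in ``Session.meta``.

Neurons spike as inhomogeneous Poisson processes whose per-bin rate is the
exponential of a sum of one-hot-binned slow-feature weights, optionally
multiplied by a 12-bin phase tuning curve (normalized to mean 1 so phase
tuning does not move the mean rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import lfilter

from ._binning import digitize, feature_edges, phase_edges
from .session import BinnedSession, Session

__all__ = [
    "RandomWalkSpec",
    "BoutSpec",
    "KinematicsSpec",
    "NeuronSpec",
    "PopulationSpec",
    "generate_kinematics",
    "bin_ground_truth",
    "simulate_neuron",
    "calibrate_baseline",
    "generate_population",
    "make_decoding_population",
    "apply_trim_effect",
]


@dataclass
class RandomWalkSpec:
    """Bounded Ornstein–Uhlenbeck drift: mean, stationary SD, time constant
    (s) and hard range (deg or cm/s)."""

    mean: float
    sd: float
    tau: float
    lo: float
    hi: float


@dataclass
class BoutSpec:
    """Exponential bout/gap durations (s) for whisking and locomotion.

    Defaults are calibrated so a 600-s session yields roughly 5,900 whisk
    cycles (whisking duty ~0.55 at a 52-ms period) and ~100 m of locomotion
    — the per-session behavioral statistics of head-fixed mice on a
    treadmill.  Whisking accompanies every locomotion bout; extra whisking
    bouts occur at rest.
    """

    whisk_bout_mean: float = 1.5
    whisk_gap_mean: float = 6.0
    run_bout_mean: float = 4.5
    run_gap_mean: float = 5.5
    min_duration: float = 0.5


@dataclass
class KinematicsSpec:
    duration: float = 600.0
    sample_rate: float = 500.0
    whisk_freq_range: tuple = (5.0, 25.0)
    mean_period_target: float = 0.052
    period_gamma_shape: float = 25.0
    midpoint_process: RandomWalkSpec = field(
        default_factory=lambda: RandomWalkSpec(mean=20.0, sd=4.0, tau=2.0, lo=8.0, hi=32.0)
    )
    amplitude_process: RandomWalkSpec = field(
        default_factory=lambda: RandomWalkSpec(mean=9.0, sd=3.0, tau=1.5, lo=2.5, hi=18.0)
    )
    bout_structure: BoutSpec = field(default_factory=BoutSpec)
    quiescent_amplitude: float = 0.5
    speed_range: tuple = (15.0, 55.0)  # per-bout mean speed draw, cm/s
    coupling: float = 0.6
    noise_sd: float = 0.2
    seed: int = 0


def _ou(rng, n, dt, spec: RandomWalkSpec) -> np.ndarray:
    """Discretized OU process with stationary SD ``spec.sd``, clipped to range."""
    a = np.exp(-dt / spec.tau)
    b = spec.sd * np.sqrt(1.0 - a * a)
    eps = rng.standard_normal(n)
    x = lfilter([b], [1.0, -a], eps)
    x += spec.mean
    return np.clip(x, spec.lo, spec.hi)


def _gate(rng, n, rate, bout_mean, gap_mean, min_dur, start_active_p=0.5):
    """Boolean bout gate from alternating exponential durations."""
    gate = np.zeros(n, dtype=bool)
    t = 0
    active = rng.random() < start_active_p
    while t < n:
        mean = bout_mean if active else gap_mean
        dur = max(min_dur, rng.exponential(mean))
        nseg = int(round(dur * rate))
        gate[t : t + nseg] = active
        t += nseg
        active = not active
    return gate


def _standardize(x):
    s = x.std()
    return (x - x.mean()) / s if s > 0 else np.zeros_like(x)


def generate_kinematics(spec: KinematicsSpec) -> Session:
    """Generate a session of whisking + locomotion with no spikes.

    Ground-truth traces (midpoint, amplitude, phase, whisking gate, cycle
    starts) are stored in ``meta`` under ``gt_*`` keys for recovery tests.
    """
    if not -1.0 <= spec.coupling <= 1.0:
        raise ValueError("coupling must lie in [-1, 1]")
    rng = np.random.default_rng(spec.seed)
    rate = spec.sample_rate
    n = int(round(spec.duration * rate))
    dt = 1.0 / rate
    bouts = spec.bout_structure

    # locomotion bouts; whisking accompanies a run bout with probability
    # |coupling| (the same knob that mixes the envelope anomalies), plus
    # independent whisking bouts at rest — so coupling 0 really decouples
    # the two behaviors while coupling 1 makes every run a whisking bout
    run_gate = _gate(rng, n, rate, bouts.run_bout_mean, bouts.run_gap_mean, bouts.min_duration)
    whisk_extra = _gate(
        rng, n, rate, bouts.whisk_bout_mean, bouts.whisk_gap_mean, bouts.min_duration
    )
    run_whisk = np.zeros(n, dtype=bool)
    edges_rw = np.flatnonzero(np.diff(run_gate.astype(int)) != 0) + 1
    for s0, s1 in zip(np.concatenate([[0], edges_rw]), np.concatenate([edges_rw, [n]])):
        if run_gate[s0] and rng.random() < abs(spec.coupling):
            run_whisk[s0:s1] = True
    whisk_gate = run_whisk | whisk_extra
    smooth = int(round(0.100 * rate))
    run_s = gaussian_filter1d(run_gate.astype(float), smooth)
    whisk_s = gaussian_filter1d(whisk_gate.astype(float), smooth)

    # speed: OU around a per-bout mean, gated and clipped non-negative
    speed_ou = _ou(rng, n, dt, RandomWalkSpec(mean=0.0, sd=6.0, tau=1.0, lo=-30.0, hi=30.0))
    bout_level = np.zeros(n)
    edges = np.flatnonzero(np.diff(run_gate.astype(int)) != 0) + 1
    seg_bounds = np.concatenate([[0], edges, [n]])
    for s0, s1 in zip(seg_bounds[:-1], seg_bounds[1:]):
        if run_gate[s0]:
            bout_level[s0:s1] = rng.uniform(*spec.speed_range)
    speed = np.clip((bout_level + speed_ou) * run_s, 0.0, None)

    # envelopes: OU anomalies coupled to the smoothed speed trace
    c = spec.coupling
    s_std = _standardize(gaussian_filter1d(speed, int(round(0.3 * rate))))
    mp_spec, am_spec = spec.midpoint_process, spec.amplitude_process
    mp_anom = c * s_std + np.sqrt(1 - c * c) * _standardize(
        _ou(rng, n, dt, replace(mp_spec, mean=0.0, lo=-np.inf, hi=np.inf))
    )
    am_anom = c * s_std + np.sqrt(1 - c * c) * _standardize(
        _ou(rng, n, dt, replace(am_spec, mean=0.0, lo=-np.inf, hi=np.inf))
    )
    midpoint = np.clip(mp_spec.mean + mp_spec.sd * mp_anom, mp_spec.lo, mp_spec.hi)
    amp_whisk = np.clip(am_spec.mean + am_spec.sd * am_anom, am_spec.lo, am_spec.hi)
    amplitude = whisk_s * amp_whisk + (1.0 - whisk_s) * spec.quiescent_amplitude

    # phase accumulator: per-cycle period from a gamma law around the target
    f_lo, f_hi = spec.whisk_freq_range
    shape = spec.period_gamma_shape
    n_cycles = int(np.ceil(spec.duration / (1.0 / f_hi))) + 2
    periods = rng.gamma(shape, spec.mean_period_target / shape, size=n_cycles)
    periods = np.clip(periods, 1.0 / f_hi, 1.0 / f_lo)
    starts_t = np.concatenate([[0.0], np.cumsum(periods)])
    t = np.arange(n) * dt
    cyc = np.searchsorted(starts_t, t, side="right") - 1
    frac = (t - starts_t[cyc]) / periods[cyc]
    phase = -np.pi + 2.0 * np.pi * frac

    angle = midpoint - amplitude * (1.0 - np.cos(phase))
    if spec.noise_sd > 0:
        angle = angle + rng.normal(0.0, spec.noise_sd, size=n)

    cycle_start_idx = np.round(starts_t[starts_t < spec.duration] * rate).astype(np.int64)
    whisking_cycles = whisk_gate[np.clip(cycle_start_idx, 0, n - 1)]
    gt_periods = periods[: len(cycle_start_idx)][whisking_cycles]

    meta = {
        "condition": "synthetic",
        "seed": spec.seed,
        "gt_midpoint": midpoint,
        "gt_amplitude": amplitude,
        "gt_phase": phase,
        "gt_whisk_gate": whisk_gate.astype(np.uint8),
        "gt_cycle_starts": cycle_start_idx,
        "gt_mean_period": float(np.mean(gt_periods)),
    }
    return Session(
        angle=angle,
        angle_rate=rate,
        speed=speed,
        speed_rate=rate,
        spikes=[],
        unit_ids=[],
        duration=spec.duration,
        meta=meta,
    )


def bin_ground_truth(session: Session, bin_width: float) -> BinnedSession:
    """Bin the generator's ground-truth features (no decomposition step)."""
    from .session import _bin_circular_mean, _bin_mean

    rate = session.angle_rate
    n_bins = int(np.floor(session.duration / bin_width))
    m = session.meta
    cyc = m["gt_cycle_starts"]
    freq = np.zeros(len(session.angle))
    for s0, s1 in zip(cyc[:-1], cyc[1:]):
        freq[s0:s1] = rate / max(s1 - s0, 1)
    features = {
        "angle": _bin_mean(session.angle, rate, bin_width, n_bins),
        "midpoint": _bin_mean(np.asarray(m["gt_midpoint"], float), rate, bin_width, n_bins),
        "amplitude": _bin_mean(np.asarray(m["gt_amplitude"], float), rate, bin_width, n_bins),
        "frequency": _bin_mean(freq, rate, bin_width, n_bins),
        "phase": _bin_circular_mean(np.asarray(m["gt_phase"], float), rate, bin_width, n_bins),
        "speed": _bin_mean(session.speed, session.speed_rate, bin_width, n_bins),
    }
    span = n_bins * bin_width
    counts = np.zeros((session.n_units, n_bins), dtype=np.int64)
    for i, st in enumerate(session.spikes):
        st = st[st < span]
        counts[i] = np.bincount(np.floor(st / bin_width).astype(np.int64), minlength=n_bins)[
            :n_bins
        ]
    bin_times = (np.arange(n_bins) + 0.5) * bin_width
    return BinnedSession(bin_width, features, counts, bin_times, list(session.unit_ids))


# ---------------------------------------------------------------------------
# neurons
# ---------------------------------------------------------------------------


@dataclass
class NeuronSpec:
    """Ground-truth tuning of one simulated neuron.

    ``slow_weights`` maps a feature name to a 20-bin weight vector (absent =
    feature not encoded); ``phase_curve`` is a 12-bin non-negative rate
    multiplier (None = no phase tuning); ``baseline_log_rate`` is
    log(expected spikes per bin); a positive ``time_shift`` makes the neuron
    encode the *future* feature value.
    """

    slow_weights: dict = field(default_factory=dict)
    phase_curve: np.ndarray | None = None
    baseline_log_rate: float = np.log(0.1)
    time_shift: float = 0.0
    seed: int = 0
    latent: "NeuronSpec | None" = None  # tuning revealed by trimming (gained units)

    @property
    def preferred_phase(self) -> float:
        if self.phase_curve is None:
            return np.nan
        centers = 0.5 * (phase_edges(12)[:-1] + phase_edges(12)[1:])
        w = np.asarray(self.phase_curve, float)
        return float(np.angle(np.sum(w * np.exp(1j * centers))))


def _rate_per_bin(spec: NeuronSpec, binned: BinnedSession, check: bool = True) -> np.ndarray:
    """Expected spike count per bin under the tuning model."""
    n = binned.n_bins
    shift_bins = int(round(spec.time_shift / binned.bin_width))

    def shifted(x):
        if shift_bins == 0:
            return x
        out = np.empty_like(x)
        if shift_bins > 0:
            out[:-shift_bins] = x[shift_bins:]
            out[-shift_bins:] = x[-1]
        else:
            out[-shift_bins:] = x[:shift_bins]
            out[: -shift_bins] = x[0]
        return out

    log_rate = np.full(n, spec.baseline_log_rate)
    for feat, w in spec.slow_weights.items():
        if feat not in binned.features:
            raise ValueError(f"binned session lacks feature {feat!r}")
        w = np.asarray(w, float)
        x = shifted(binned.features[feat])
        idx = digitize(x, feature_edges(x, len(w)))
        log_rate = log_rate + w[idx]
    lam = np.exp(log_rate)
    if spec.phase_curve is not None:
        pc = np.asarray(spec.phase_curve, float)
        mult = pc / pc.mean()
        idx = digitize(shifted(binned.features["phase"]), phase_edges(len(pc)))
        lam = lam * mult[idx]
    mean_hz = lam.mean() / binned.bin_width if n else 0.0
    if not np.isfinite(lam).all() or (check and mean_hz > 200.0):
        worst = max(spec.slow_weights, key=lambda f: np.ptp(spec.slow_weights[f]), default="baseline")
        raise ValueError(f"rate overflow (mean {mean_hz:.1f} Hz); check weights for {worst!r}")
    return lam


def calibrate_baseline(spec: NeuronSpec, binned: BinnedSession, target_rate_hz: float) -> NeuronSpec:
    """Return a copy of ``spec`` whose mean rate on ``binned`` equals the target."""
    probe = replace(spec, baseline_log_rate=0.0)
    lam = _rate_per_bin(probe, binned, check=False)
    base = np.log(target_rate_hz * binned.bin_width) - np.log(lam.mean())
    return replace(spec, baseline_log_rate=float(base))


def simulate_neuron(spec: NeuronSpec, binned: BinnedSession, rng=None) -> np.ndarray:
    """Poisson spike counts per bin from the neuron's tuning model."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    return rng.poisson(_rate_per_bin(spec, binned))


def counts_to_spike_times(counts: np.ndarray, bin_width: float, rng) -> np.ndarray:
    """Scatter per-bin counts into sorted spike times, uniform within bins."""
    idx = np.repeat(np.arange(len(counts)), counts)
    return np.sort((idx + rng.random(len(idx))) * bin_width)


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------


@dataclass
class PopulationSpec:
    n_neurons: int = 40
    mix_1d: float = 0.59
    mix_multi: float = 0.41
    fraction_phase_tuned: float = 0.5
    rate_range_hz: tuple = (5.0, 30.0)
    weight_span: float = 2.0  # ln-units from weakest to strongest bin
    phase_kappa: float = 2.0
    trim_effect: dict | None = None  # label -> fraction over {none,lost,gained,modified}
    sim_bin_width: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if abs(self.mix_1d + self.mix_multi - 1.0) > 1e-6:
            raise ValueError("mix_1d + mix_multi must sum to 1")


def _random_slow_weights(rng, features, span):
    """Centered ramps or bumps over 20 bins, span ``span`` ln-units each."""
    out = {}
    x = np.linspace(0.0, 1.0, 20)
    for f in features:
        kind = rng.choice(["ramp_up", "ramp_down", "bump"])
        if kind == "ramp_up":
            w = x * span
        elif kind == "ramp_down":
            w = (1.0 - x) * span
        else:
            mu = rng.uniform(0.25, 0.75)
            w = span * np.exp(-0.5 * ((x - mu) / 0.18) ** 2)
        out[f] = w - w.mean()
    return out


def _von_mises_curve(mu, kappa, n_bins=12):
    centers = 0.5 * (phase_edges(n_bins)[:-1] + phase_edges(n_bins)[1:])
    return np.exp(kappa * np.cos(centers - mu))


def _draw_neuron(rng, pspec: PopulationSpec, phase_tuned: bool, slow: bool = True):
    features = ()
    if slow:
        if rng.random() < pspec.mix_1d:
            k = 1
        else:
            k = rng.choice([2, 3])
        features = tuple(
            rng.choice(["speed", "midpoint", "amplitude"], size=k, replace=False)
        )
    # per-feature span shrinks as 1/sqrt(k) so the total dynamic range of a
    # multi-feature neuron stays physiological
    span = pspec.weight_span / np.sqrt(max(len(features), 1))
    weights = _random_slow_weights(rng, features, span)
    curve = (
        _von_mises_curve(rng.uniform(-np.pi, np.pi), pspec.phase_kappa)
        if phase_tuned
        else None
    )
    return NeuronSpec(
        slow_weights=weights,
        phase_curve=curve,
        seed=int(rng.integers(2**31 - 1)),
    )


def generate_population(pspec: PopulationSpec, kspec: KinematicsSpec):
    """Simulate a population with known ground-truth tuning.

    Returns ``(session, truth, specs)``: the session with spikes attached,
    a DataFrame of each unit's true encoded features / preferred phase /
    time shift / trim label, and the per-unit :class:`NeuronSpec` list.
    """
    rng = np.random.default_rng(pspec.seed)
    session = generate_kinematics(kspec)
    binned = bin_ground_truth(session, pspec.sim_bin_width)

    labels = ["none"] * pspec.n_neurons
    if pspec.trim_effect:
        names = list(pspec.trim_effect)
        probs = np.asarray([pspec.trim_effect[k] for k in names], float)
        if abs(probs.sum() - 1.0) > 1e-6:
            raise ValueError("trim_effect fractions must sum to 1")
        labels = list(rng.choice(names, size=pspec.n_neurons, p=probs))

    specs, rows, spikes, unit_ids = [], [], [], []
    for i in range(pspec.n_neurons):
        phase_tuned = rng.random() < pspec.fraction_phase_tuned
        spec = _draw_neuron(rng, pspec, phase_tuned)
        target = rng.uniform(*pspec.rate_range_hz)
        if labels[i] == "gained":
            # untuned pre-trim; the latent tuned spec is revealed post-trim
            latent = calibrate_baseline(spec, binned, target)
            spec = NeuronSpec(slow_weights={}, phase_curve=None, seed=spec.seed, latent=latent)
        spec = calibrate_baseline(spec, binned, target)
        specs.append(spec)
        counts = simulate_neuron(spec, binned, rng=np.random.default_rng(spec.seed))
        spikes.append(counts_to_spike_times(counts, pspec.sim_bin_width, np.random.default_rng(spec.seed + 1)))
        uid = f"u{i:03d}"
        unit_ids.append(uid)
        rows.append(
            {
                "unit_id": uid,
                "features": ",".join(sorted(spec.slow_weights)),
                "n_features": len(spec.slow_weights),
                "phase_tuned": spec.phase_curve is not None,
                "preferred_phase": spec.preferred_phase,
                "time_shift": spec.time_shift,
                "target_rate_hz": target,
                "trim_label": labels[i],
            }
        )
    session.spikes = [np.asarray(s) for s in spikes]
    session.unit_ids = unit_ids
    session.validate()
    truth = pd.DataFrame(rows)
    return session, truth, specs


def make_decoding_population(
    n_slow: int = 20,
    n_phase: int = 20,
    kspec: KinematicsSpec | None = None,
    rate_range_hz=(5.0, 30.0),
    weight_span: float = 2.0,
    phase_kappa: float = 2.0,
    phase_slow_fraction: float = 0.53,
    sim_bin_width: float = 0.005,
    seed: int = 0,
):
    """Mixed population for position decoding: slow units + phase-tuned units.

    The slow units encode midpoint and/or amplitude (the envelope of whisker
    position); the phase-tuned units carry the fast, within-cycle component.
    As observed in the recorded population, about half of phase-tuned units
    (``phase_slow_fraction``) additionally encode a slow feature, i.e. their
    phase response is gain-modulated by amplitude or midpoint through the
    multiplicative rate model.  Returns ``(session, truth, specs)``.
    """
    if kspec is None:
        kspec = KinematicsSpec(seed=seed)
    rng = np.random.default_rng(seed + 1)
    session = generate_kinematics(kspec)
    binned = bin_ground_truth(session, sim_bin_width)

    specs, rows, spikes, unit_ids = [], [], [], []
    for i in range(n_slow + n_phase):
        if i < n_slow:
            feats = ("midpoint",) if i % 2 == 0 else ("midpoint", "amplitude")
            weights = _random_slow_weights(rng, feats, weight_span)
            spec = NeuronSpec(slow_weights=weights, seed=int(rng.integers(2**31 - 1)))
        else:
            mu = -np.pi + 2 * np.pi * (i - n_slow) / n_phase
            weights = {}
            if rng.random() < phase_slow_fraction:
                gain_feat = rng.choice(["amplitude", "midpoint"])
                weights = _random_slow_weights(rng, (gain_feat,), weight_span)
            spec = NeuronSpec(
                slow_weights=weights,
                phase_curve=_von_mises_curve(mu, phase_kappa),
                seed=int(rng.integers(2**31 - 1)),
            )
        target = rng.uniform(*rate_range_hz)
        spec = calibrate_baseline(spec, binned, target)
        specs.append(spec)
        counts = simulate_neuron(spec, binned, rng=np.random.default_rng(spec.seed))
        spikes.append(
            counts_to_spike_times(counts, sim_bin_width, np.random.default_rng(spec.seed + 1))
        )
        uid = f"u{i:03d}"
        unit_ids.append(uid)
        rows.append(
            {
                "unit_id": uid,
                "features": ",".join(sorted(spec.slow_weights)),
                "phase_tuned": spec.phase_curve is not None,
                "preferred_phase": spec.preferred_phase,
                "target_rate_hz": target,
            }
        )
    session.spikes = [np.asarray(s) for s in spikes]
    session.unit_ids = unit_ids
    session.validate()
    return session, pd.DataFrame(rows), specs


def _trimmed_spec(spec: NeuronSpec, label: str, rng) -> NeuronSpec:
    if label == "none":
        return replace(spec)
    if label == "lost":
        return replace(spec, slow_weights={}, phase_curve=None, latent=None)
    if label == "gained":
        if spec.latent is None:
            raise ValueError("'gained' unit has no latent post-trim tuning")
        return replace(spec.latent)
    if label == "modified":
        # shift AND weaken: a pure tuning-curve shift leaves the refit LNP
        # model's predictability unchanged and would be undetectable by a
        # performance-based test
        new_w = {f: 0.5 * np.roll(w, 5) for f, w in spec.slow_weights.items()}
        new_pc = np.roll(spec.phase_curve, 6) if spec.phase_curve is not None else None
        return replace(spec, slow_weights=new_w, phase_curve=new_pc)
    raise ValueError(f"unknown trim label {label!r}")


def apply_trim_effect(
    session: Session,
    truth: pd.DataFrame,
    specs: list,
    kspec_post: KinematicsSpec | None = None,
    rate_factor: float = 0.8,
    sim_bin_width: float = 0.005,
    seed: int = 1,
):
    """Build the post-trim condition for a simulated population.

    Each unit's tuning is transformed per its ``trim_label`` (lost → flat,
    gained → latent tuning revealed, modified → tuning curve rolled 5 bins /
    phase curve rotated 180°, none → unchanged) and all mean rates are
    scaled by ``rate_factor`` (default 0.8, emulating the overall firing
    rate reduction after whisker trimming).  Returns
    ``(post_session, post_specs)``.
    """
    if kspec_post is None:
        kspec_post = KinematicsSpec(duration=session.duration, seed=seed + 7919)
    rng = np.random.default_rng(seed)
    post_session = generate_kinematics(kspec_post)
    binned = bin_ground_truth(post_session, sim_bin_width)

    post_specs, spikes = [], []
    for spec, (_, row) in zip(specs, truth.iterrows()):
        pspec_post = _trimmed_spec(spec, row["trim_label"], rng)
        pspec_post = calibrate_baseline(
            pspec_post, binned, rate_factor * row["target_rate_hz"]
        )
        post_specs.append(pspec_post)
        counts = simulate_neuron(pspec_post, binned, rng=np.random.default_rng(pspec_post.seed + 2))
        spikes.append(
            counts_to_spike_times(counts, sim_bin_width, np.random.default_rng(pspec_post.seed + 3))
        )
    post_session.spikes = [np.asarray(s) for s in spikes]
    post_session.unit_ids = list(session.unit_ids)
    post_session.meta["condition"] = "post_trim"
    post_session.validate()
    return post_session, post_specs
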