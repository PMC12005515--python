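"""Kinematic decomposition of a whisker-angle trace.

The angle trace θ(t) is split into slow and fast components:

* **midpoint** (the protracted envelope bound, a.k.a. offset ``O``) — the
  upper envelope through protraction peaks;
* **amplitude** ``A`` — half the envelope width;
* **phase** ``φ`` — the angle of the analytic signal of the 5–50 Hz
  band-passed trace, with 0 at the most protracted point of the cycle and
  ±π at the most retracted;
* **frequency** ``F`` — the per-cycle reciprocal period, held constant
  within a cycle and 0 during quiescence.

The arithmetic inverse is ``θ̂ = midpoint − amplitude · (1 − cos φ)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import Akima1DInterpolator
from scipy.signal import butter, find_peaks, hilbert, sosfiltfilt

#: default whisking band, Hz
BAND = (5.0, 50.0)
#: peak/trough detection: minimum prominence (deg) and separation (s)
PEAK_PROMINENCE = 1.0
PEAK_MIN_SEPARATION = 0.020
#: plausible whisk-cycle duration bounds (s)
CYCLE_MIN, CYCLE_MAX = 0.020, 0.200


@dataclass
class WhiskDecomposition:
    angle: np.ndarray
    rate: float
    midpoint: np.ndarray
    amplitude: np.ndarray
    phase: np.ndarray
    frequency: np.ndarray
    envelope_upper: np.ndarray
    envelope_lower: np.ndarray
    protraction_onsets: np.ndarray  # sample indices
    cycle_bounds: np.ndarray  # (n_cycles, 2) [start, end) sample indices
    envelope_degenerate: bool = False

    @property
    def cycle_periods(self) -> np.ndarray:
        """Cycle durations in seconds."""
        if len(self.cycle_bounds) == 0:
            return np.empty(0)
        return (self.cycle_bounds[:, 1] - self.cycle_bounds[:, 0]) / self.rate


def _interp_extrema(idx: np.ndarray, values: np.ndarray, n: int) -> np.ndarray:
    """Akima interpolation through extrema, edges held at nearest extremum."""
    x = idx.astype(float)
    y = values.astype(float)
    if x[0] > 0:
        x = np.concatenate([[0.0], x])
        y = np.concatenate([[y[0]], y])
    if x[-1] < n - 1:
        x = np.concatenate([x, [float(n - 1)]])
        y = np.concatenate([y, [y[-1]]])
    return Akima1DInterpolator(x, y)(np.arange(n, dtype=float))


def compute_envelope(angle: np.ndarray, rate: float):
    """Upper/lower envelopes via Akima interpolation of peaks/troughs.

    Returns ``(upper, lower, degenerate)``.  When no oscillation is
    detectable (< 2 peaks or troughs) both envelopes are the trace itself
    and ``degenerate`` is True.
    """
    angle = np.asarray(angle, dtype=float)
    dist = max(1, int(round(PEAK_MIN_SEPARATION * rate)))
    peaks, _ = find_peaks(angle, prominence=PEAK_PROMINENCE, distance=dist)
    troughs, _ = find_peaks(-angle, prominence=PEAK_PROMINENCE, distance=dist)
    if len(peaks) < 2 or len(troughs) < 2:
        return angle.copy(), angle.copy(), True
    n = len(angle)
    upper = _interp_extrema(peaks, angle[peaks], n)
    lower = _interp_extrema(troughs, angle[troughs], n)
    # Akima can cross where amplitude collapses; keep the ordering invariant
    bad = upper < lower
    if bad.any():
        mid = 0.5 * (upper[bad] + lower[bad])
        upper[bad] = mid
        lower[bad] = mid
    return upper, lower, False


def compute_phase(angle: np.ndarray, rate: float, band=BAND) -> np.ndarray:
    """Hilbert phase of the band-passed angle trace.

    Zero-phase (forward-backward) 4th-order Butterworth band-pass keeps the
    phase undistorted; the analytic-signal angle is 0 where the band-passed
    trace peaks (most protracted) and ±π at the troughs (most retracted).
    """
    angle = np.asarray(angle, dtype=float)
    if rate <= 100:
        raise ValueError("sample rate must exceed 100 Hz for phase extraction")
    if len(angle) < 10 * rate / band[0]:
        raise ValueError("trace too short: need >= 10 cycles of the low cutoff")
    sos = butter(4, band, btype="bandpass", fs=rate, output="sos")
    filtered = sosfiltfilt(sos, angle)
    return np.angle(hilbert(filtered))


def segment_cycles(phase: np.ndarray, rate: float, amplitude=None, min_amplitude: float = 1.0):
    """Protraction onsets and whisk-cycle bounds from the phase trace.

    An onset is an upward crossing of phase through −π (the wrap point,
    i.e. the most retracted moment).  Cycles outside [20, 200] ms are
    discarded as non-whisking, as are cycles whose mean movement amplitude
    falls below ``min_amplitude`` degrees (the analytic phase of a flat,
    noisy trace still wraps, but those wraps are not whisks).
    """
    wraps = np.nonzero(np.diff(phase) < -np.pi)[0] + 1
    bounds = []
    for s, e in zip(wraps[:-1], wraps[1:]):
        period = (e - s) / rate
        if not CYCLE_MIN <= period <= CYCLE_MAX:
            continue
        if amplitude is not None and np.mean(amplitude[s:e]) < min_amplitude:
            continue
        bounds.append((s, e))
    bounds = np.asarray(bounds, dtype=np.int64).reshape(-1, 2)
    onsets = bounds[:, 0] if len(bounds) else np.empty(0, dtype=np.int64)
    return onsets, bounds


def decompose(angle: np.ndarray, rate: float) -> WhiskDecomposition:
    """Full decomposition: envelopes, midpoint, amplitude, phase, cycles."""
    angle = np.asarray(angle, dtype=float)
    upper, lower, degenerate = compute_envelope(angle, rate)
    midpoint = upper
    amplitude = 0.5 * (upper - lower)
    phase = compute_phase(angle, rate)
    onsets, bounds = segment_cycles(phase, rate, amplitude=amplitude)
    frequency = np.zeros_like(angle)
    for s, e in bounds:
        frequency[s:e] = rate / (e - s)
    return WhiskDecomposition(
        angle=angle,
        rate=rate,
        midpoint=midpoint,
        amplitude=amplitude,
        phase=phase,
        frequency=frequency,
        envelope_upper=upper,
        envelope_lower=lower,
        protraction_onsets=onsets,
        cycle_bounds=bounds,
        envelope_degenerate=degenerate,
    )


def reconstruct_angle(decomp: WhiskDecomposition):
    """Arithmetic reconstruction θ̂ = midpoint − amplitude·(1 − cos φ).

    Returns ``(theta_hat, r_squared)`` where R² is computed against the
    original angle trace.
    """
    theta = decomp.midpoint - decomp.amplitude * (1.0 - np.cos(decomp.phase))
    resid = decomp.angle - theta
    ss_tot = np.sum((decomp.angle - decomp.angle.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else np.nan
    return theta, r2


def _best_split(y: np.ndarray, csum: np.ndarray, csum2: np.ndarray, lo: int, hi: int, min_seg: int):
    """Best single split of y[lo:hi]; returns (gain, split index) or (0, -1)."""

    def sse(a, b):
        n = b - a
        s = csum[b] - csum[a]
        s2 = csum2[b] - csum2[a]
        return s2 - s * s / n

    total = sse(lo, hi)
    best_gain, best_k = 0.0, -1
    for k in range(lo + min_seg, hi - min_seg + 1):
        g = total - sse(lo, k) - sse(k, hi)
        if g > best_gain:
            best_gain, best_k = g, k
    return best_gain, best_k


def detect_offset_changepoints(
    series: np.ndarray,
    rate: float,
    penalty: float | None = None,
    max_changepoints: int = 10,
    min_segment: float = 0.25,
):
    """Change-points of a (midpoint) series by binary segmentation.

    Greedy recursive splitting minimizing within-segment squared residuals;
    a split is kept while its SSE reduction exceeds ``penalty`` (default
    ``2 · var(diff)/2 · log(n)``, a BIC-flavored scale on the local noise
    variance).  Returns sorted change-point times in seconds.
    """
    y = np.asarray(series, dtype=float)
    n = len(y)
    min_seg = max(2, int(round(min_segment * rate)))
    if n <= 2 * min_seg:
        return np.empty(0)
    if penalty is None:
        noise_var = 0.5 * np.var(np.diff(y)) if n > 1 else 0.0
        penalty = max(2.0 * noise_var * np.log(n), 1e-12)
    csum = np.concatenate([[0.0], np.cumsum(y)])
    csum2 = np.concatenate([[0.0], np.cumsum(y * y)])

    segments = [(0, n)]
    cps = []
    while segments and len(cps) < max_changepoints:
        gains = []
        for lo, hi in segments:
            if hi - lo >= 2 * min_seg:
                gains.append((*_best_split(y, csum, csum2, lo, hi, min_seg), lo, hi))
            else:
                gains.append((0.0, -1, lo, hi))
        gains.sort(reverse=True)
        gain, k, lo, hi = gains[0]
        if k < 0 or gain <= penalty:
            break
        cps.append(k)
        segments.remove((lo, hi))
        segments.extend([(lo, k), (k, hi)])
    return np.sort(np.asarray(cps, dtype=float)) / rate


def classify_feature_speed(
    series: np.ndarray,
    rate: float,
    whisk_period: float = 0.052,
    max_lag: float = 1.0,
):
    """Classify a feature as 'slow' or 'fast' from its autocorrelation decay.

    Fast features (phase, white noise) lose half their autocorrelation
    within one mean whisk cycle; slow features (midpoint, amplitude) do not.
    Returns ``(label, lags_s, acf)``.
    """
    y = np.asarray(series, dtype=float) - np.mean(series)
    n = len(y)
    nlag = min(n - 1, int(round(max_lag * rate)))
    denom = np.dot(y, y)
    if denom == 0:
        raise ValueError("zero-variance series")
    acf = np.array([np.dot(y[: n - k], y[k:]) / denom for k in range(nlag + 1)])
    lags = np.arange(nlag + 1) / rate
    below = np.nonzero(acf < 0.5)[0]
    t_half = lags[below[0]] if below.size else np.inf
    label = "fast" if t_half <= whisk_period else "slow"
    return label, lags, acf
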