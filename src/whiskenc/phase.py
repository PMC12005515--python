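"""Phase tuning: spike-triggered circular statistics on the whisk cycle.

Spike phases are read off the Hilbert-phase trace at spike times, restricted
to whisking epochs (amplitude above a small threshold — phase is undefined
during quiescence).  Rates are occupancy-normalized within 12 non-overlapping
30° bins spanning [−π, π].  Significance of phase locking uses the Rayleigh
test on the spike-phase sample; the preferred phase is the circular mean and
the modulation depth is (maxFR − minFR) / meanFR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._binning import digitize, phase_edges
from .kinematics import WhiskDecomposition

N_PHASE_BINS = 12
WHISKING_AMPLITUDE_DEG = 2.5
MIN_SPIKES = 50


@dataclass
class PhaseTuning:
    bin_edges: np.ndarray  # (13,)
    rates: np.ndarray  # spikes/s per bin
    occupancy: np.ndarray  # s per bin
    preferred_phase: float  # rad, circular mean of spike phases
    modulation_depth: float
    rayleigh_p: float
    n_spikes: int
    low_count: bool = False

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def circular_mean(angles: np.ndarray) -> float:
    return float(np.angle(np.mean(np.exp(1j * np.asarray(angles)))))


def resultant_length(angles: np.ndarray) -> float:
    return float(np.abs(np.mean(np.exp(1j * np.asarray(angles)))))


def rayleigh_test(angles: np.ndarray) -> float:
    """Rayleigh test of circular uniformity; returns the p-value.

    Uses the standard small-sample-corrected approximation
    p = exp(√(1 + 4n + 4(n² − R²)) − (1 + 2n)) with R = n·R̄.
    Requires n ≥ 10 (returns NaN below).
    """
    angles = np.asarray(angles, float)
    n = len(angles)
    if n < 10:
        return np.nan
    R = n * resultant_length(angles)
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n * n - R * R)) - (1.0 + 2.0 * n))
    return float(min(p, 1.0))


def _spike_phase_samples(spike_times, phase, rate, mask=None):
    """Phase at each spike (nearest sample), optionally gated by a mask."""
    idx = np.clip(np.round(np.asarray(spike_times) * rate).astype(np.int64), 0, len(phase) - 1)
    if mask is not None:
        idx = idx[mask[idx]]
    return phase[idx], idx


def phase_tuning_curve(
    spike_times: np.ndarray,
    decomp: WhiskDecomposition,
    amp_threshold: float = WHISKING_AMPLITUDE_DEG,
    n_bins: int = N_PHASE_BINS,
) -> PhaseTuning:
    """Occupancy-normalized 12-bin phase tuning curve of one unit."""
    rate = decomp.rate
    mask = decomp.amplitude >= amp_threshold
    edges = phase_edges(n_bins)
    occ_counts = np.bincount(digitize(decomp.phase[mask], edges), minlength=n_bins)
    occupancy = occ_counts / rate

    sp_phase, _ = _spike_phase_samples(spike_times, decomp.phase, rate, mask)
    counts = np.bincount(digitize(sp_phase, edges), minlength=n_bins).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(occupancy > 0, counts / occupancy, np.nan)

    n_spk = len(sp_phase)
    low = n_spk < MIN_SPIKES
    if low:
        pref, depth, p = np.nan, np.nan, np.nan
    else:
        pref = circular_mean(sp_phase)
        valid = rates[np.isfinite(rates)]
        depth = float((valid.max() - valid.min()) / valid.mean()) if valid.mean() > 0 else np.nan
        p = rayleigh_test(sp_phase)
    return PhaseTuning(
        bin_edges=edges,
        rates=rates,
        occupancy=occupancy,
        preferred_phase=pref,
        modulation_depth=depth,
        rayleigh_p=p,
        n_spikes=n_spk,
        low_count=low,
    )


def modulation_depth(rates: np.ndarray) -> float:
    """(maxFR − minFR) / meanFR of a tuning curve."""
    r = np.asarray(rates, float)
    r = r[np.isfinite(r)]
    return float((r.max() - r.min()) / r.mean())


def segregate_by_slow_feature(
    spike_times: np.ndarray,
    decomp: WhiskDecomposition,
    feature: str = "midpoint",
    amp_threshold: float = WHISKING_AMPLITUDE_DEG,
):
    """Phase curves for whisk cycles split at the median cycle-wise feature.

    Returns ``(lower_half, upper_half)`` :class:`PhaseTuning` pairs.
    """
    values = getattr(decomp, feature)
    bounds = decomp.cycle_bounds
    if len(bounds) < 2:
        raise ValueError("cycle segmentation required")
    cyc_val = np.array([values[s:e].mean() for s, e in bounds])
    med = np.median(cyc_val)
    halves = []
    for upper in (False, True):
        sel = cyc_val > med if upper else cyc_val <= med
        mask = np.zeros(len(decomp.phase), dtype=bool)
        for s, e in bounds[sel]:
            mask[s:e] = True
        sub = _masked_phase_tuning(spike_times, decomp, mask, amp_threshold)
        halves.append(sub)
    return halves[0], halves[1]


def _masked_phase_tuning(spike_times, decomp, cycle_mask, amp_threshold):
    mask = cycle_mask & (decomp.amplitude >= amp_threshold)
    edges = phase_edges(N_PHASE_BINS)
    occ = np.bincount(digitize(decomp.phase[mask], edges), minlength=N_PHASE_BINS) / decomp.rate
    sp_phase, _ = _spike_phase_samples(spike_times, decomp.phase, decomp.rate, mask)
    counts = np.bincount(digitize(sp_phase, edges), minlength=N_PHASE_BINS).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(occ > 0, counts / occ, np.nan)
    n_spk = len(sp_phase)
    low = n_spk < MIN_SPIKES
    pref = circular_mean(sp_phase) if n_spk else np.nan
    valid = rates[np.isfinite(rates)]
    depth = (
        float((valid.max() - valid.min()) / valid.mean())
        if valid.size and valid.mean() > 0
        else np.nan
    )
    return PhaseTuning(
        bin_edges=edges,
        rates=rates,
        occupancy=occ,
        preferred_phase=pref,
        modulation_depth=depth,
        rayleigh_p=rayleigh_test(sp_phase) if not low else np.nan,
        n_spikes=n_spk,
        low_count=low,
    )


def whisks_by_preceding_spikes(
    spike_times: np.ndarray,
    decomp: WhiskDecomposition,
    groups=((0, 0), (1, 3), (4, np.inf)),
    align_window: float = 0.100,
):
    """Mean whisker-position traces grouped by spikes in the preceding cycle.

    For each whisk cycle the spike count within the *preceding* full cycle
    assigns the cycle to a group; each group's protraction-onset-aligned
    mean angle trace and mean midpoint/amplitude are returned as a dict
    ``group -> {"trace", "n", "midpoint", "amplitude"}`` (empty groups
    omitted).
    """
    bounds = decomp.cycle_bounds
    if len(bounds) < 2:
        raise ValueError("cycle segmentation required")
    st = np.sort(np.asarray(spike_times))
    rate = decomp.rate
    n_trace = int(round(align_window * rate))
    results = {}
    # consecutive cycles only: the preceding cycle must abut the current one
    prev_counts, starts = [], []
    for (ps, pe), (cs, ce) in zip(bounds[:-1], bounds[1:]):
        if pe != cs:
            continue
        c = np.searchsorted(st, pe / rate) - np.searchsorted(st, ps / rate)
        if cs + n_trace <= len(decomp.angle):
            prev_counts.append(c)
            starts.append(cs)
    prev_counts = np.asarray(prev_counts)
    starts = np.asarray(starts)
    for lo, hi in groups:
        sel = (prev_counts >= lo) & (prev_counts <= hi)
        if not sel.any():
            continue
        idx = starts[sel][:, None] + np.arange(n_trace)[None, :]
        results[(lo, hi)] = {
            "trace": decomp.angle[idx].mean(axis=0),
            "n": int(sel.sum()),
            "midpoint": float(np.mean([decomp.midpoint[s : s + n_trace].mean() for s in starts[sel]])),
            "amplitude": float(np.mean([decomp.amplitude[s : s + n_trace].mean() for s in starts[sel]])),
        }
    return results
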