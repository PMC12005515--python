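"""Pre/post whisker-trim comparison of self-motion tuning.

After trimming, each unit's slow-feature tuning is re-assessed with an
independently fit LNP model on behavior-range-matched data and categorized
as lost / gained / modified / no_change / untuned_both; phase tuning is
categorized from the Rayleigh significance in each condition and the
Pearson correlation between the 12-bin curves.  Population firing-rate
changes are tested on samples down-sampled to identical 2D
(position × speed) occupancy histograms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._binning import digitize
from .lnp import forward_search, tuning_curve
from .phase import PhaseTuning
from .session import BinnedSession

CATEGORIES = ("lost", "gained", "modified", "no_change", "untuned_both")


@dataclass
class RangeMatch:
    pre_mask: np.ndarray
    post_mask: np.ndarray
    retained_pre: float
    retained_post: float
    bounds: dict  # feature -> (lo, hi)


def match_behavior_range(
    pre: BinnedSession, post: BinnedSession, features=("speed", "midpoint", "amplitude")
) -> RangeMatch:
    """Restrict both conditions to the intersection of feature ranges."""
    pre_mask = np.ones(pre.n_bins, dtype=bool)
    post_mask = np.ones(post.n_bins, dtype=bool)
    bounds = {}
    for f in features:
        a, b = np.asarray(pre.features[f], float), np.asarray(post.features[f], float)
        lo = max(a.min(), b.min())
        hi = min(a.max(), b.max())
        if hi <= lo:
            raise ValueError(f"feature {f!r}: no overlap between conditions")
        bounds[f] = (lo, hi)
        pre_mask &= (a >= lo) & (a <= hi)
        post_mask &= (b >= lo) & (b <= hi)
    if not pre_mask.any() or not post_mask.any():
        raise ValueError("empty range intersection")
    return RangeMatch(
        pre_mask=pre_mask,
        post_mask=post_mask,
        retained_pre=float(pre_mask.mean()),
        retained_post=float(post_mask.mean()),
        bounds=bounds,
    )


def _masked(binned: BinnedSession, mask) -> BinnedSession:
    return BinnedSession(
        binned.bin_width,
        {k: np.asarray(v)[mask] for k, v in binned.features.items()},
        binned.spike_counts[:, mask],
        binned.bin_times[mask],
        binned.unit_ids,
    )


@dataclass
class SlowChange:
    category: str
    pre_selected: tuple
    post_selected: tuple
    t_p: float | None = None
    tuning_r: float | None = None
    tuning_p: float | None = None


def classify_slow_change(
    pre: BinnedSession,
    post: BinnedSession,
    unit: int,
    alpha: float = 0.05,
    range_match: RangeMatch | None = None,
    beta: float = 5e-2,
) -> SlowChange:
    """Categorize one unit's slow-feature tuning change across trimming.

    Forward search runs independently per condition on range-matched data;
    tuned-pre-only → lost, tuned-post-only → gained, tuned in both → a
    two-sample t-test over the 10 per-fold LLH values decides modified vs
    no_change (corroborated by the Pearson correlation of the pre/post
    tuning curves of the best pre feature), tuned in neither → untuned_both.
    """
    if range_match is None:
        range_match = match_behavior_range(pre, post)
    pre_m = _masked(pre, range_match.pre_mask)
    post_m = _masked(post, range_match.post_mask)
    sel_pre = forward_search(pre_m, pre_m.spike_counts[unit], alpha=alpha, beta=beta)
    sel_post = forward_search(post_m, post_m.spike_counts[unit], alpha=alpha, beta=beta)
    if sel_pre.unclassified and sel_post.unclassified:
        return SlowChange("untuned_both", (), ())
    if not sel_pre.unclassified and sel_post.unclassified:
        return SlowChange("lost", sel_pre.selected, ())
    if sel_pre.unclassified and not sel_post.unclassified:
        return SlowChange("gained", (), sel_post.selected)

    llh_pre = sel_pre.llh_table[sel_pre.selected]
    best_feat = sel_pre.selected[0]
    post_model = tuple(sorted(set(sel_pre.selected)))
    if post_model not in sel_post.llh_table:
        from .lnp import build_design_matrix, crossval_llh

        dm = build_design_matrix(post_m, post_model)
        llh_post = crossval_llh(dm, post_m.spike_counts[unit], post_m.bin_width, beta).fold_llh
    else:
        llh_post = sel_post.llh_table[post_model]
    t_p = float(stats.ttest_ind(llh_pre, llh_post).pvalue)

    _, tc_pre, _ = tuning_curve(pre_m, pre_m.spike_counts[unit], best_feat)
    _, tc_post, _ = tuning_curve(post_m, post_m.spike_counts[unit], best_feat)
    ok = np.isfinite(tc_pre) & np.isfinite(tc_post)
    if ok.sum() >= 3:
        r, rp = stats.pearsonr(tc_pre[ok], tc_post[ok])
    else:
        r, rp = np.nan, np.nan
    # "modified" needs both a significant LLH change over folds and
    # corroborating shape evidence (pre/post curves no longer correlated);
    # fold LLHs are not independent samples, so the t-test alone is
    # anti-conservative across sessions with different behavior
    shape_changed = not (np.isfinite(rp) and rp < alpha and r > 0)
    category = "modified" if (t_p < alpha and shape_changed) else "no_change"
    return SlowChange(category, sel_pre.selected, sel_post.selected, t_p, float(r), float(rp))


@dataclass
class PhaseChange:
    category: str | None
    pearson_r: float | None = None
    pearson_p: float | None = None
    undefined: bool = False


def classify_phase_change(
    pre: PhaseTuning, post: PhaseTuning, alpha: float = 0.05
) -> PhaseChange:
    """Categorize a phase-tuning change from pre/post 12-bin curves."""
    if pre.low_count or post.low_count:
        return PhaseChange(None, undefined=True)
    tuned_pre = pre.rayleigh_p < alpha
    tuned_post = post.rayleigh_p < alpha
    if tuned_pre and not tuned_post:
        return PhaseChange("lost")
    if not tuned_pre and tuned_post:
        return PhaseChange("gained")
    if not tuned_pre and not tuned_post:
        return PhaseChange("untuned_both")
    ok = np.isfinite(pre.rates) & np.isfinite(post.rates)
    r, p = stats.pearsonr(pre.rates[ok], post.rates[ok])
    # an anti-correlated (rotated) curve is a shape change, not stability
    category = "no_change" if (p < alpha and r > 0) else "modified"
    return PhaseChange(category, float(r), float(p))


@dataclass
class OccupancyMatch:
    pre_mask: np.ndarray
    post_mask: np.ndarray
    position_edges: np.ndarray
    speed_edges: np.ndarray


def match_occupancy_2d(
    pre: BinnedSession,
    post: BinnedSession,
    n_position_bins: int = 20,
    n_speed_bins: int = 20,
    seed: int = 0,
    position_feature: str = "angle",
) -> OccupancyMatch:
    """Down-sample both conditions to identical 2D occupancy histograms.

    Each joint (position × speed) bin keeps min(pre, post) samples, chosen
    uniformly at random with the given seed; the resulting masked occupancy
    histograms are equal bin-wise by construction.
    """
    rng = np.random.default_rng(seed)
    p_pre = np.asarray(pre.features[position_feature], float)
    p_post = np.asarray(post.features[position_feature], float)
    s_pre = np.asarray(pre.features["speed"], float)
    s_post = np.asarray(post.features["speed"], float)
    pe = np.linspace(
        min(p_pre.min(), p_post.min()), max(p_pre.max(), p_post.max()), n_position_bins + 1
    )
    se = np.linspace(
        min(s_pre.min(), s_post.min()), max(s_pre.max(), s_post.max()), n_speed_bins + 1
    )
    joint_pre = digitize(p_pre, pe) * n_speed_bins + digitize(s_pre, se)
    joint_post = digitize(p_post, pe) * n_speed_bins + digitize(s_post, se)
    pre_mask = np.zeros(pre.n_bins, dtype=bool)
    post_mask = np.zeros(post.n_bins, dtype=bool)
    overlap = False
    for b in np.union1d(joint_pre, joint_post):
        ia = np.flatnonzero(joint_pre == b)
        ib = np.flatnonzero(joint_post == b)
        keep = min(len(ia), len(ib))
        if keep == 0:
            continue
        overlap = True
        pre_mask[rng.choice(ia, size=keep, replace=False)] = True
        post_mask[rng.choice(ib, size=keep, replace=False)] = True
    if not overlap:
        raise ValueError("zero joint-occupancy overlap between conditions")
    return OccupancyMatch(pre_mask, post_mask, pe, se)


@dataclass
class MatchedRateResult:
    pre_rates: np.ndarray  # Hz per unit
    post_rates: np.ndarray
    wilcoxon_p: float | None
    direction: str | None
    suppressed: bool = False


def matched_rate_test(
    pre: BinnedSession, post: BinnedSession, match: OccupancyMatch
) -> MatchedRateResult:
    """Per-unit mean rates on occupancy-matched samples + paired Wilcoxon."""
    pre_rates = pre.spike_counts[:, match.pre_mask].mean(axis=1) / pre.bin_width
    post_rates = post.spike_counts[:, match.post_mask].mean(axis=1) / post.bin_width
    if len(pre_rates) < 6:
        return MatchedRateResult(pre_rates, post_rates, None, None, suppressed=True)
    d = post_rates - pre_rates
    if np.allclose(d, 0):
        return MatchedRateResult(pre_rates, post_rates, 1.0, "none")
    p = float(stats.wilcoxon(pre_rates, post_rates).pvalue)
    direction = "decrease" if np.median(d) < 0 else "increase"
    return MatchedRateResult(pre_rates, post_rates, p, direction)
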