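"""Linear-nonlinear Poisson (LNP) encoding models over binned slow features.

Each feature (locomotion speed L, whisker midpoint O, amplitude A, whisking
frequency F) is one-hot coded into 20 equal-width bins over its observed
range.  The model sets the expected spike count in bin ``t`` to

    E[n_t] = exp( Σ_f  X_f^t · W_f )

and the weight vectors W_f are found by maximizing the Poisson
log-likelihood with a smoothness penalty β on adjacent-bin weight
differences within each block.  Model performance is the cross-validated
log-likelihood improvement over the mean-firing-rate model, in bits per
spike:

    LLH = (negLLH_meanFR − negLLH_model) / ln 2

with each negative log-likelihood spike-normalized,
``(1/Σn_t) Σ_t [ r̂_t − n_t log r̂_t + log n_t! ]``.  Model selection is a
greedy forward search: start from the best single-feature model and add
features only while the enlarged model significantly improves held-out
likelihood (one-sided Wilcoxon signed-rank over the 10 folds, α = 0.05);
a neuron whose best model does not beat the mean-rate model is unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln
from scipy.stats import wilcoxon

from ._binning import digitize, feature_edges
from .session import SLOW_FEATURES, BinnedSession

N_FEATURE_BINS = 20
DEFAULT_BETA = 5e-2
N_FOLDS = 10
FOLD_CHUNK = 100  # bins per contiguous chunk dealt round-robin into folds

#: canonical feature order L < O < A < F (tie-break order)
FEATURE_ORDER = SLOW_FEATURES


@dataclass
class DesignMatrix:
    """One-hot design stored as per-feature bin-index arrays."""

    features: tuple
    indices: dict  # feature -> (n_rows,) int bin index
    edges: dict  # feature -> (21,) bin edges
    n_rows: int
    n_bins: int = N_FEATURE_BINS

    def block(self, feature: str) -> np.ndarray:
        """Dense one-hot block for one feature (rows sum to 1)."""
        out = np.zeros((self.n_rows, self.n_bins))
        out[np.arange(self.n_rows), self.indices[feature]] = 1.0
        return out

    def subset(self, features) -> "DesignMatrix":
        features = tuple(f for f in FEATURE_ORDER if f in features)
        return DesignMatrix(
            features,
            {f: self.indices[f] for f in features},
            {f: self.edges[f] for f in features},
            self.n_rows,
            self.n_bins,
        )

    def rows(self, mask) -> "DesignMatrix":
        return DesignMatrix(
            self.features,
            {f: self.indices[f][mask] for f in self.features},
            self.edges,
            int(np.sum(mask)) if mask.dtype == bool else len(mask),
            self.n_bins,
        )


@dataclass
class LNPFit:
    weights: dict  # feature -> (20,) weights
    beta: float
    dt: float
    converged: bool = True
    fold_llh: np.ndarray | None = None  # bits/spike per fold (if cross-validated)
    zero_spike_folds: np.ndarray | None = None

    @property
    def mean_llh(self) -> float:
        return float(np.mean(self.fold_llh)) if self.fold_llh is not None else np.nan

    def predict_counts(self, dm: DesignMatrix) -> np.ndarray:
        log_rate = np.zeros(dm.n_rows)
        for f, w in self.weights.items():
            log_rate += w[dm.indices[f]]
        return np.exp(log_rate)


@dataclass
class SelectionResult:
    selected: tuple  # () = unclassified
    llh_table: dict  # model tuple -> per-fold LLH array
    pvalues: dict  # (smaller, larger) model tuples -> p
    unclassified: bool

    def mean_llh(self, model) -> float:
        return float(np.mean(self.llh_table[tuple(model)]))


@dataclass
class Contributions:
    values: dict  # feature -> normalized contribution
    raw: dict
    undefined: bool = False


def build_design_matrix(binned: BinnedSession, features) -> DesignMatrix:
    """One-hot design over 20 equal-width bins per feature."""
    features = tuple(f for f in FEATURE_ORDER if f in features)
    indices, edges = {}, {}
    for f in features:
        if f not in binned.features:
            raise KeyError(f"feature {f!r} not in binned session")
        x = np.asarray(binned.features[f], float)
        try:
            e = feature_edges(x, N_FEATURE_BINS)
        except ValueError as err:
            raise ValueError(f"feature {f!r} has zero range") from err
        edges[f] = e
        indices[f] = digitize(x, e)
    return DesignMatrix(features, indices, edges, binned.n_bins)


def _pack(weights: dict, features) -> np.ndarray:
    return np.concatenate([weights[f] for f in features])


def _unpack(w: np.ndarray, features, n_bins=N_FEATURE_BINS) -> dict:
    return {f: w[i * n_bins : (i + 1) * n_bins] for i, f in enumerate(features)}


#: tiny L2 term pinning the between-block flat direction (blocks can trade a
#: constant against each other at no likelihood or smoothness cost)
RIDGE_EPS = 1e-6


def _objective(w, dm: DesignMatrix, counts, beta):
    nb = dm.n_bins
    feats = dm.features
    log_rate = np.zeros(dm.n_rows)
    for i, f in enumerate(feats):
        log_rate += w[i * nb : i * nb + nb][dm.indices[f]]
    lam = np.exp(log_rate)
    scale = 1.0 / dm.n_rows  # scale-free objective: tolerances are per bin
    nll = float(np.sum(lam) - np.dot(counts, log_rate))
    grad = np.empty_like(w)
    resid = lam - counts
    pen = RIDGE_EPS * float(np.dot(w, w))
    for i, f in enumerate(feats):
        wf = w[i * nb : i * nb + nb]
        g = np.bincount(dm.indices[f], weights=resid, minlength=nb)
        d = np.diff(wf)
        pen += beta * float(np.dot(d, d))
        gp = 2.0 * RIDGE_EPS * wf
        gp[:-1] -= 2.0 * beta * d
        gp[1:] += 2.0 * beta * d
        grad[i * nb : i * nb + nb] = g + gp
    return (nll + pen) * scale, grad * scale


def fit_lnp(
    dm: DesignMatrix,
    counts: np.ndarray,
    dt: float,
    beta: float = DEFAULT_BETA,
    max_iter: int = 1000,
) -> LNPFit:
    """Penalized Poisson ML fit; deterministic from zero initialization."""
    counts = np.asarray(counts, float)
    if len(counts) != dm.n_rows:
        raise ValueError("counts not aligned to design matrix rows")
    w0 = np.zeros(len(dm.features) * dm.n_bins)
    res = minimize(
        _objective,
        w0,
        args=(dm, counts, beta),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": 1e-6, "ftol": 1e-14},
    )
    if not res.success and np.max(np.abs(res.jac)) > 1e-3:
        raise RuntimeError(f"LNP fit did not converge: {res.message} (|g|={np.max(np.abs(res.jac)):.2e})")
    return LNPFit(weights=_unpack(res.x, dm.features), beta=beta, dt=dt, converged=res.success)


def poisson_negllh(pred_counts: np.ndarray, counts: np.ndarray) -> float:
    """Spike-normalized Poisson negative log-likelihood.

    ``(1/Σn_t) Σ_t [ r̂_t − n_t log r̂_t + log n_t! ]`` with r̂ the expected
    count per bin.  Returns NaN when the window contains no spikes.
    """
    counts = np.asarray(counts, float)
    total = counts.sum()
    if total == 0:
        return np.nan
    pred = np.asarray(pred_counts, float)
    with np.errstate(divide="ignore"):
        log_pred = np.log(pred)
    terms = pred - counts * log_pred + gammaln(counts + 1.0)
    return float(np.sum(terms) / total)


def llh_bits_per_spike(pred_counts, counts, train_mean_count) -> float:
    """Held-out LLH improvement over the mean-rate model, bits/spike."""
    nll_model = poisson_negllh(pred_counts, counts)
    nll_mean = poisson_negllh(np.full(len(counts), train_mean_count), counts)
    if np.isnan(nll_model):
        return 0.0
    return (nll_mean - nll_model) / np.log(2.0)


def make_folds(n_rows: int, n_folds: int = N_FOLDS, chunk: int = FOLD_CHUNK):
    """Interleaved contiguous chunks dealt round-robin into folds."""
    chunk_ids = np.arange(n_rows) // chunk
    return [np.flatnonzero(chunk_ids % n_folds == k) for k in range(n_folds)]


def crossval_llh(
    dm: DesignMatrix,
    counts: np.ndarray,
    dt: float,
    beta: float = DEFAULT_BETA,
    n_folds: int = N_FOLDS,
) -> LNPFit:
    """10-fold cross-validated LLH (bits/spike); folds are interleaved chunks."""
    counts = np.asarray(counts, float)
    folds = make_folds(dm.n_rows, n_folds)
    llh = np.zeros(n_folds)
    flags = np.zeros(n_folds, dtype=bool)
    fit_full = fit_lnp(dm, counts, dt, beta)
    all_idx = np.arange(dm.n_rows)
    for k, test_idx in enumerate(folds):
        train_mask = np.ones(dm.n_rows, dtype=bool)
        train_mask[test_idx] = False
        train_idx = all_idx[train_mask]
        fit = fit_lnp(dm.rows(train_idx), counts[train_idx], dt, beta)
        pred = fit.predict_counts(dm.rows(test_idx))
        if counts[test_idx].sum() == 0:
            llh[k] = 0.0
            flags[k] = True
        else:
            llh[k] = llh_bits_per_spike(pred, counts[test_idx], counts[train_idx].mean())
    fit_full.fold_llh = llh
    fit_full.zero_spike_folds = flags
    return fit_full


def _signed_rank_greater(x: np.ndarray, y=None) -> float:
    """One-sided Wilcoxon signed-rank p for median(x − y) > 0."""
    d = x if y is None else x - y
    if np.allclose(d, 0):
        return 1.0
    return float(wilcoxon(d, alternative="greater", zero_method="wilcox").pvalue)


def forward_search(
    binned: BinnedSession,
    counts: np.ndarray,
    dt: float | None = None,
    alpha: float = 0.05,
    features=FEATURE_ORDER,
    beta: float = DEFAULT_BETA,
) -> SelectionResult:
    """Greedy forward feature selection over the LNP model family."""
    if dt is None:
        dt = binned.bin_width
    usable = []
    for f in features:
        x = binned.features[f]
        if np.ptp(x) > 0:
            usable.append(f)
    full_dm = build_design_matrix(binned, usable)
    table, pvalues = {}, {}

    def cv(model):
        model = tuple(f for f in FEATURE_ORDER if f in model)
        if model not in table:
            table[model] = crossval_llh(full_dm.subset(model), counts, dt, beta).fold_llh
        return table[model]

    singles = [(f,) for f in usable]
    means = [np.mean(cv(m)) for m in singles]
    current = singles[int(np.argmax(means))]
    # grow while a larger model significantly improves held-out LLH
    while len(current) < len(usable):
        candidates = [
            tuple(f for f in FEATURE_ORDER if f in current + (extra,))
            for extra in usable
            if extra not in current
        ]
        cand_means = [np.mean(cv(m)) for m in candidates]
        best = candidates[int(np.argmax(cand_means))]
        p = _signed_rank_greater(cv(best), cv(current))
        pvalues[(current, best)] = p
        if p < alpha:
            current = best
        else:
            break
    p_vs_mean = _signed_rank_greater(cv(current))
    pvalues[((), current)] = p_vs_mean
    unclassified = p_vs_mean >= alpha
    return SelectionResult(
        selected=() if unclassified else current,
        llh_table=table,
        pvalues=pvalues,
        unclassified=unclassified,
    )


def feature_contributions(
    binned: BinnedSession,
    counts: np.ndarray,
    selection: SelectionResult,
    dt: float | None = None,
    beta: float = DEFAULT_BETA,
    features=("speed", "midpoint", "amplitude"),
) -> Contributions:
    """Normalized per-feature LLH contributions over {L, O, A}.

    contrib(f) = LLH(selected ∪ {f}) − LLH((selected ∪ {f}) \\ {f});
    negatives are clamped to 0 and the result normalized to sum 1.
    """
    if dt is None:
        dt = binned.bin_width
    full_dm = build_design_matrix(
        binned, [f for f in FEATURE_ORDER if np.ptp(binned.features[f]) > 0]
    )
    table = dict(selection.llh_table)

    def mean_llh(model):
        model = tuple(f for f in FEATURE_ORDER if f in model)
        if not model:
            return 0.0
        if model not in table:
            table[model] = crossval_llh(full_dm.subset(model), counts, dt, beta).fold_llh
        return float(np.mean(table[model]))

    sel = set(selection.selected)
    raw = {}
    for f in features:
        with_f = sel | {f}
        without_f = with_f - {f}
        raw[f] = mean_llh(with_f) - mean_llh(without_f)
    clamped = {f: max(v, 0.0) for f, v in raw.items()}
    total = sum(clamped.values())
    if total <= 0:
        return Contributions(values={f: np.nan for f in features}, raw=raw, undefined=True)
    return Contributions(values={f: v / total for f, v in clamped.items()}, raw=raw)


def tuning_curve(
    binned: BinnedSession, counts: np.ndarray, feature: str, n_bins: int = N_FEATURE_BINS
):
    """Mean ± SEM firing rate (Hz) within 20 equal feature bins.

    Empty bins are NaN, not zero.  Returns ``(bin_centers, mean, sem)``.
    """
    x = np.asarray(binned.features[feature], float)
    edges = feature_edges(x, n_bins)
    idx = digitize(x, edges)
    rate = np.asarray(counts, float) / binned.bin_width
    mean = np.full(n_bins, np.nan)
    sem = np.full(n_bins, np.nan)
    for b in range(n_bins):
        r = rate[idx == b]
        if r.size:
            mean[b] = r.mean()
            sem[b] = r.std(ddof=1) / np.sqrt(r.size) if r.size > 1 else np.nan
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, mean, sem


def event_triggered_rate(
    spike_times: np.ndarray,
    events: np.ndarray,
    duration: float,
    window: float = 2.0,
    bin_width: float = 0.050,
):
    """Peri-event time histogram: mean ± SEM firing rate around events.

    Events whose window exceeds the session bounds are dropped; the count of
    dropped events is returned.  Returns ``(lags, mean, sem, n_dropped)``.
    """
    events = np.asarray(events, float)
    ok = (events - window >= 0) & (events + window <= duration)
    n_dropped = int(np.sum(~ok))
    events = events[ok]
    if len(events) < 5:
        raise ValueError("need >= 5 in-bounds events")
    edges = np.arange(-window, window + bin_width / 2, bin_width)
    lags = 0.5 * (edges[:-1] + edges[1:])
    per_event = np.empty((len(events), len(lags)))
    st = np.sort(np.asarray(spike_times, float))
    for i, ev in enumerate(events):
        rel = st[(st >= ev - window) & (st <= ev + window)] - ev
        per_event[i], _ = np.histogram(rel, bins=edges)
    per_event /= bin_width
    mean = per_event.mean(axis=0)
    sem = per_event.std(axis=0, ddof=1) / np.sqrt(len(events))
    return lags, mean, sem, n_dropped
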