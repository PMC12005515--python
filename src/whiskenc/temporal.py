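"""Temporal structure of encoding: time-shifted models and temporal kernels.

Two complementary views of *when* a neuron's preferred feature predicts its
spiking:

* **time-shifted LNP models** — the single best feature is displaced by each
  shift in {−200 … +200} ms (positive = future feature predicts current
  spikes), refit at 25-ms resolution, and the cross-validated LLH plotted
  against shift.  The *temporal bias* is the normalized AUC difference
  between future and past shifts; the *preferred shift* is the LLH argmax.
* **temporal kernel GLM** — a single ridge model over a ±10-bin (20-ms)
  window of all slow features at once, with a circular-shift permutation
  null for significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.linear_model import Ridge

from .lnp import DEFAULT_BETA, build_design_matrix, crossval_llh
from .session import BinnedSession

#: feature shifts, ms (past < 0 < future)
SHIFTS_MS = (-200, -150, -100, -75, -50, -25, 0, 25, 50, 75, 100, 150, 200)
SHIFT_BIN_WIDTH = 0.025
KERNEL_BIN_WIDTH = 0.020
KERNEL_LAGS = np.arange(-10, 11)  # in 20-ms bins → −200 … +200 ms


@dataclass
class TemporalCurve:
    shifts_ms: np.ndarray
    llh: np.ndarray  # mean CV LLH per shift, bits/spike
    feature: str

    @property
    def preferred_shift(self) -> float:
        return float(self.shifts_ms[int(np.argmax(self.llh))])


@dataclass
class TemporalKernelFit:
    features: tuple
    coef: np.ndarray  # (n_features, 21)
    lags_ms: np.ndarray
    alpha: float
    r2: float
    intercept: float
    feature_scale: dict  # feature -> (mean, sd) used for standardization
    null_r2: np.ndarray | None = None
    p_value: float | None = None

    @property
    def significant(self) -> bool | None:
        return None if self.p_value is None else bool(self.p_value < 0.05)


def _shift_series(x: np.ndarray, k: int) -> np.ndarray:
    """x displaced so out[t] = x[t + k]; edges hold the boundary value."""
    if k == 0:
        return x.copy()
    out = np.empty_like(x)
    if k > 0:
        out[:-k] = x[k:]
        out[-k:] = x[-1]
    else:
        out[-k:] = x[:k]
        out[:-k] = x[0]
    return out


def fit_time_shifted(
    binned: BinnedSession,
    counts: np.ndarray,
    feature: str,
    shifts_ms=SHIFTS_MS,
    beta: float = DEFAULT_BETA,
) -> TemporalCurve:
    """LLH-vs-shift curve for single-feature LNP models at 25-ms bins."""
    bw = binned.bin_width
    counts = np.asarray(counts, float)
    shifts = np.asarray(shifts_ms, float)
    ks = np.round(shifts / 1000.0 / bw).astype(int)
    kmax = int(np.max(np.abs(ks)))
    n = binned.n_bins
    valid = slice(kmax, n - kmax if kmax else n)
    x = np.asarray(binned.features[feature], float)
    llh = np.zeros(len(shifts))
    if np.ptp(x) == 0:
        # a constant feature predicts nothing at any displacement; the model
        # reduces to the mean-rate model (LLH identically 0)
        return TemporalCurve(shifts_ms=shifts, llh=llh, feature=feature)
    for i, k in enumerate(ks):
        shifted = BinnedSession(
            bw,
            {feature: _shift_series(x, k)[valid]},
            binned.spike_counts[:, valid],
            binned.bin_times[valid],
            binned.unit_ids,
        )
        dm = build_design_matrix(shifted, (feature,))
        llh[i] = crossval_llh(dm, counts[valid], bw, beta).mean_llh
    return TemporalCurve(shifts_ms=shifts, llh=llh, feature=feature)


def temporal_bias(curve: TemporalCurve):
    """Normalized future-vs-past AUC of the baseline-subtracted LLH curve.

    The curve minimum is shifted to zero before integrating (LLH can be
    negative); shift 0 belongs to neither side.  Returns ``(bias, defined)``
    with bias in [−1, 1], NaN when the total area vanishes.
    """
    y = curve.llh - np.min(curve.llh)
    x = curve.shifts_ms
    pos = x > 0
    neg = x < 0
    auc_pos = np.trapezoid(y[pos], x[pos])
    auc_neg = np.trapezoid(y[neg][::-1], -x[neg][::-1])
    total = auc_pos + auc_neg
    if total <= 0:
        return np.nan, False
    return float((auc_pos - auc_neg) / total), True


def cluster_temporal_curves(curves: list, k: int = 3, seed: int = 0):
    """k-means over min-max-normalized LLH-vs-shift curves.

    Clusters are relabeled by ascending template temporal bias so that
    label 0 = past-, 1 = present-, 2 = future-biased (for k = 3).
    Returns ``(labels, templates)``.
    """
    if len(curves) < k:
        raise ValueError(f"need at least {k} curves")
    M = np.stack([c.llh for c in curves]).astype(float)
    lo = M.min(axis=1, keepdims=True)
    rng_ = M.max(axis=1, keepdims=True) - lo
    rng_[rng_ == 0] = 1.0
    M = (M - lo) / rng_
    km = KMeans(n_clusters=k, n_init=50, random_state=seed).fit(M)
    shifts = curves[0].shifts_ms
    templates = km.cluster_centers_
    biases = [
        temporal_bias(TemporalCurve(shifts, t, curves[0].feature))[0] for t in templates
    ]
    order = np.argsort(biases)
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return relabel[km.labels_], templates[order]


def xcorr_lag(rate: np.ndarray, feature: np.ndarray, bin_width: float, max_lag: float = 0.200):
    """Lag (s) of the largest absolute normalized cross-correlation.

    Sign convention matches the time-shifted models: a positive lag means
    the rate correlates with *future* feature values, a negative lag with
    past values.  Ties break toward zero.  Returns
    ``(lag_s, peak_correlation)``.
    """
    r = np.asarray(rate, float) - np.mean(rate)
    f = np.asarray(feature, float) - np.mean(feature)
    if r.std() == 0 or f.std() == 0:
        raise ValueError("zero-variance input")
    kmax = int(round(max_lag / bin_width))
    n = len(r)
    cc = np.empty(2 * kmax + 1)
    for i, k in enumerate(range(-kmax, kmax + 1)):
        if k >= 0:
            a, b = r[: n - k], f[k:]
        else:
            a, b = r[-k:], f[: n + k]
        cc[i] = np.dot(a, b) / (n * r.std() * f.std())
    lags = np.arange(-kmax, kmax + 1) * bin_width
    best = np.max(np.abs(cc))
    cand = np.flatnonzero(np.abs(cc) >= best - 1e-15)
    pick = cand[np.argmin(np.abs(lags[cand]))]
    return float(lags[pick]), float(cc[pick])


def _lagged_design(binned: BinnedSession, features, lags=KERNEL_LAGS):
    """Standardized lagged feature matrix; edge rows are dropped."""
    kmax = int(np.max(np.abs(lags)))
    n = binned.n_bins
    valid = np.arange(kmax, n - kmax)
    cols, scale, used = [], {}, []
    for f in features:
        x = np.asarray(binned.features[f], float)
        if np.ptp(x) == 0:
            continue  # degenerate feature excluded
        mu, sd = x.mean(), x.std()
        scale[f] = (mu, sd)
        xs = (x - mu) / sd
        for k in lags:
            cols.append(xs[valid + k])
        used.append(f)
    X = np.column_stack(cols)
    return X, valid, tuple(used), scale


def fit_temporal_kernel(
    binned: BinnedSession,
    counts: np.ndarray,
    features=("speed", "midpoint", "amplitude"),
    lags=KERNEL_LAGS,
    alphas=None,
    test_fraction: float = 0.2,
    cv_folds: int = 5,
) -> TemporalKernelFit:
    """Windowed ridge GLM over ±10 lags of the slow features at 20-ms bins.

    The ridge penalty is chosen by 5-fold CV on the (contiguous) first 80%
    of rows; R² is reported on the held-out final 20%.
    """
    if alphas is None:
        alphas = np.logspace(-2, 5, 8)
    counts = np.asarray(counts, float)
    X, valid, used, scale = _lagged_design(binned, features, lags)
    y = counts[valid]
    if len(y) < 1000:
        raise ValueError("need >= 1000 usable bins after windowing")
    n_test = int(round(test_fraction * len(y)))
    Xtr, ytr = X[:-n_test], y[:-n_test]
    Xte, yte = X[-n_test:], y[-n_test:]

    bounds = np.linspace(0, len(ytr), cv_folds + 1).astype(int)
    cv_err = []
    for a in alphas:
        err = 0.0
        for i in range(cv_folds):
            mask = np.ones(len(ytr), dtype=bool)
            mask[bounds[i] : bounds[i + 1]] = False
            model = Ridge(alpha=a).fit(Xtr[mask], ytr[mask])
            pred = model.predict(Xtr[~mask])
            err += np.sum((pred - ytr[~mask]) ** 2)
        cv_err.append(err)
    alpha = float(alphas[int(np.argmin(cv_err))])
    model = Ridge(alpha=alpha).fit(Xtr, ytr)
    r2 = float(model.score(Xte, yte))
    coef = model.coef_.reshape(len(used), len(lags))
    return TemporalKernelFit(
        features=used,
        coef=coef,
        lags_ms=np.asarray(lags) * binned.bin_width * 1000.0,
        alpha=alpha,
        r2=r2,
        intercept=float(model.intercept_),
        feature_scale=scale,
    )


def permutation_significance(
    binned: BinnedSession,
    counts: np.ndarray,
    fit: TemporalKernelFit,
    n_perm: int = 1000,
    seed: int = 0,
    min_shift: float = 1.0,
    features=None,
) -> TemporalKernelFit:
    """Circular-shift permutation null for the kernel model's test R².

    Each permutation rotates the spike-count series by a uniform offset of
    at least ``min_shift`` seconds (preserving its autocorrelation), refits
    at the already-chosen penalty, and records held-out R².  The p-value is
    the fraction of null R² values ≥ the observed one.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    counts = np.asarray(counts, float)
    if features is None:
        features = fit.features
    X, valid, _, _ = _lagged_design(binned, features, np.round(fit.lags_ms / 1000.0 / binned.bin_width).astype(int))
    n = len(counts)
    kmin = int(np.ceil(min_shift / binned.bin_width))
    n_test = int(round(0.2 * len(valid)))
    null = np.empty(n_perm)
    for i in range(n_perm):
        off = int(rng.integers(kmin, n - kmin))
        y = np.roll(counts, off)[valid]
        model = Ridge(alpha=fit.alpha).fit(X[:-n_test], y[:-n_test])
        null[i] = model.score(X[-n_test:], y[-n_test:])
    p = float((np.sum(null >= fit.r2) + 1) / (n_perm + 1))
    fit.null_r2 = null
    fit.p_value = p
    return fit


def kernel_preferences(fit: TemporalKernelFit):
    """Preferred feature (largest Σ|coef|) and preferred time (lag of the
    maximum coefficient within that feature's window).

    Ties in the feature AUC break in the canonical L < O < A order and are
    flagged.  Returns ``(feature, time_ms, tied)``.
    """
    auc = np.sum(np.abs(fit.coef), axis=1)
    best = int(np.argmax(auc))
    tied = bool(np.sum(np.isclose(auc, auc[best])) > 1)
    k = int(np.argmax(fit.coef[best]))
    return fit.features[best], float(fit.lags_ms[k]), tied
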