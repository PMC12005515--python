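"""Lagged ridge decoding of whisker position and locomotion speed.

Whisker position is decoded at 15-ms resolution from an 11-bin window of
population spike counts (5 preceding, 1 concurrent, 5 following — 165 ms);
locomotion speed at 100-ms resolution from a 9-bin window.  The ridge
penalty is selected by 10-fold cross-validation on the first 80% of bins
and R² is reported on the contiguous final 20%, so train and test never
interleave in time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Ridge

from .session import BinnedSession, Session


@dataclass
class DecoderConfig:
    target: str = "position"  # 'position' (angle) or 'speed'
    bin_width: float = 0.015
    window: int = 11
    alphas: np.ndarray = field(default_factory=lambda: np.logspace(-2, 6, 9))
    cv_folds: int = 10
    test_fraction: float = 0.20
    seed: int = 0

    def __post_init__(self):
        if self.window % 2 == 0:
            raise ValueError("window must be odd (centered)")
        if not 0 < self.test_fraction <= 0.5:
            raise ValueError("test fraction must be in (0, 0.5]")

    @classmethod
    def for_speed(cls, **kw):
        kw.setdefault("target", "speed")
        kw.setdefault("bin_width", 0.100)
        kw.setdefault("window", 9)
        return cls(**kw)


@dataclass
class DecoderResult:
    coef: np.ndarray  # (n_units, window)
    alpha: float
    r2: float
    predicted: np.ndarray
    actual: np.ndarray
    n_units: int


def build_lagged_matrix(counts: np.ndarray, window: int = 11):
    """Concatenate each unit's counts at bins t−h … t+h (unit-major).

    Rows without a full window are dropped.  Returns ``(X, valid_bins,
    constant_columns)`` where ``constant_columns`` flags degenerate columns.
    """
    counts = np.atleast_2d(np.asarray(counts, float))
    n_units, n_bins = counts.shape
    h = window // 2
    valid = np.arange(h, n_bins - h)
    X = np.empty((len(valid), n_units * window))
    for u in range(n_units):
        for j, k in enumerate(range(-h, h + 1)):
            X[:, u * window + j] = counts[u, valid + k]
    constant = np.flatnonzero(np.ptp(X, axis=0) == 0)
    return X, valid, constant


def fit_decoder(X: np.ndarray, y: np.ndarray, config: DecoderConfig) -> DecoderResult:
    """Ridge fit with CV-chosen penalty; R² on the contiguous final 20%."""
    if len(X) != len(y):
        raise ValueError("rows(X) must equal len(y)")
    if len(config.alphas) == 0:
        raise ValueError("empty penalty grid")
    n_test = int(round(config.test_fraction * len(y)))
    Xtr, ytr = X[:-n_test], y[:-n_test]
    Xte, yte = X[-n_test:], y[-n_test:]
    bounds = np.linspace(0, len(ytr), config.cv_folds + 1).astype(int)
    errs = []
    for a in config.alphas:
        err = 0.0
        for i in range(config.cv_folds):
            mask = np.ones(len(ytr), dtype=bool)
            mask[bounds[i] : bounds[i + 1]] = False
            m = Ridge(alpha=a).fit(Xtr[mask], ytr[mask])
            err += np.sum((m.predict(Xtr[~mask]) - ytr[~mask]) ** 2)
        errs.append(err)
    alpha = float(config.alphas[int(np.argmin(errs))])
    model = Ridge(alpha=alpha).fit(Xtr, ytr)
    pred = model.predict(Xte)
    ss_res = np.sum((yte - pred) ** 2)
    ss_tot = np.sum((yte - yte.mean()) ** 2)
    r2 = float(1.0 - ss_res / ss_tot)
    coef = model.coef_
    n_units = X.shape[1] // config.window
    if n_units * config.window == X.shape[1]:
        coef = coef.reshape(n_units, config.window)  # per-unit per-lag weights
    return DecoderResult(
        coef=coef,
        alpha=alpha,
        r2=r2,
        predicted=pred,
        actual=np.asarray(yte),
        n_units=n_units,
    )


def _target_series(binned: BinnedSession, target: str) -> np.ndarray:
    if target == "position":
        return np.asarray(binned.features["angle"], float)
    if target == "speed":
        return np.asarray(binned.features["speed"], float)
    raise ValueError(f"unknown target {target!r}")


def decode_session(
    session_or_binned,
    config: DecoderConfig,
    unit_indices=None,
    ground_truth_features: bool = False,
) -> DecoderResult:
    """Bin a session at the decoder resolution and decode the target trace."""
    if isinstance(session_or_binned, BinnedSession):
        binned = session_or_binned
    elif ground_truth_features:
        from .synth import bin_ground_truth

        binned = bin_ground_truth(session_or_binned, config.bin_width)
    else:
        from .session import bin_session

        binned = bin_session(session_or_binned, config.bin_width)
    counts = binned.spike_counts
    if unit_indices is not None:
        counts = counts[np.asarray(unit_indices)]
    X, valid, _ = build_lagged_matrix(counts, config.window)
    y = _target_series(binned, config.target)[valid]
    return fit_decoder(X, y, config)


def subsample_curve(
    binned: BinnedSession,
    config: DecoderConfig,
    sizes,
    encoding_units=None,
    n_repeats: int = 10,
):
    """Decoding R² vs population size, ``n_repeats`` random unit draws each.

    Returns a list of dicts ``{"size", "mean", "sd", "r2s"}``; sizes larger
    than the available unit pool are skipped (reported with NaN mean).
    """
    rng = np.random.default_rng(config.seed)
    pool = (
        np.arange(binned.spike_counts.shape[0])
        if encoding_units is None
        else np.asarray(encoding_units)
    )
    out = []
    for size in sizes:
        if size > len(pool):
            out.append({"size": size, "mean": np.nan, "sd": np.nan, "r2s": [], "skipped": True})
            continue
        r2s = []
        for _ in range(n_repeats):
            sel = rng.choice(pool, size=size, replace=False)
            r2s.append(decode_session(binned, config, unit_indices=sel).r2)
        r2s = np.asarray(r2s)
        out.append(
            {"size": size, "mean": float(r2s.mean()), "sd": float(r2s.std(ddof=1)) if len(r2s) > 1 else 0.0, "r2s": r2s, "skipped": False}
        )
    return out


def shuffle_control(
    binned: BinnedSession,
    config: DecoderConfig,
    seed: int = 0,
    min_shift: float = 5.0,
) -> DecoderResult:
    """Decode after circularly shifting each unit's spike counts.

    Each unit's count series is rotated by an independent uniform offset of
    at least ``min_shift`` seconds; kinematics are untouched, so any
    residual R² reflects chance structure only.
    """
    rng = np.random.default_rng(seed)
    counts = binned.spike_counts.copy()
    n = counts.shape[1]
    kmin = int(np.ceil(min_shift / config.bin_width))
    if kmin >= n - kmin:
        raise ValueError("session too short for the requested minimum shift")
    for u in range(counts.shape[0]):
        counts[u] = np.roll(counts[u], int(rng.integers(kmin, n - kmin)))
    shuffled = BinnedSession(
        binned.bin_width, binned.features, counts, binned.bin_times, binned.unit_ids
    )
    return decode_session(shuffled, config)
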