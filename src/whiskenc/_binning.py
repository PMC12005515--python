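"""Shared feature-binning helpers (one-hot index convention).

Every feature is discretized into ``n_bins`` equal-width bins spanning its
observed range; values at the maximum edge fall in the last bin.  Phase uses
the fixed range [−π, π].  The same convention drives both the encoding
design matrices and the spike simulator, so simulated tuning is expressed in
exactly the basis the models estimate.
"""

from __future__ import annotations

import numpy as np


def feature_edges(values: np.ndarray, n_bins: int = 20) -> np.ndarray:
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi <= lo:
        raise ValueError("feature has zero range")
    return np.linspace(lo, hi, n_bins + 1)


def phase_edges(n_bins: int = 12) -> np.ndarray:
    return np.linspace(-np.pi, np.pi, n_bins + 1)


def digitize(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Bin indices in [0, n_bins); values at/above the top edge → last bin."""
    idx = np.searchsorted(edges, values, side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)
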