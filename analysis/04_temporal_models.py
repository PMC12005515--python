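#!/usr/bin/env python
"""Temporal preference of each tuned unit: time-shifted models, temporal
bias, preferred shift, k-means clusters, and rate/feature cross-correlation.
"""

import argparse
import os

import numpy as np
import pandas as pd

from whiskenc.lnp import forward_search
from whiskenc.session import bin_session, read_session
from whiskenc.temporal import cluster_temporal_curves, fit_time_shifted, temporal_bias, xcorr_lag


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results")
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    session = read_session(os.path.join(args.out, "session.h5"))
    b25 = bin_session(session, 0.025)

    rows, curves, curve_units = [], [], []
    for u, uid in enumerate(b25.unit_ids):
        sel = forward_search(b25, b25.spike_counts[u])
        if not sel.selected:
            continue
        best = sel.selected[0]
        curve = fit_time_shifted(b25, b25.spike_counts[u], best)
        bias, defined = temporal_bias(curve)
        rate = b25.spike_counts[u] / b25.bin_width
        lag, peak = xcorr_lag(rate, np.asarray(b25.features[best], float), b25.bin_width)
        curves.append(curve)
        curve_units.append(uid)
        rows.append(
            {
                "unit_id": uid,
                "best_feature": best,
                "preferred_shift_ms": curve.preferred_shift,
                "temporal_bias": bias if defined else np.nan,
                "xcorr_lag_ms": lag * 1000,
                "xcorr_peak": peak,
            }
        )
    df = pd.DataFrame(rows)
    if len(curves) >= 3:
        labels, _ = cluster_temporal_curves(curves, k=3, seed=args.seed)
        df["cluster"] = [["past", "present", "future"][k] for k in labels]
    path = os.path.join(args.out, "temporal_models.csv")
    df.to_csv(path, index=False)
    print(df.to_string(index=False))
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
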