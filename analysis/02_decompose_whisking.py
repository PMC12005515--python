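#!/usr/bin/env python
"""Decompose the session's whisker angle into midpoint, amplitude, and phase,
and verify the arithmetic reconstruction midpoint − amplitude·(1 − cos φ).

Reads results/session.h5 (from 01_simulate_session.py); writes a per-sample
decomposition summary and prints the reconstruction R² — on synthetic
sessions this should sit at or above the 0.95 level seen with real tracking.
"""

import argparse
import os

import numpy as np
import pandas as pd

from whiskenc.kinematics import classify_feature_speed, decompose, reconstruct_angle
from whiskenc.session import read_session


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    session = read_session(os.path.join(args.out, "session.h5"))
    d = decompose(session.angle, session.angle_rate)
    theta_hat, r2 = reconstruct_angle(d)

    print(f"whisk cycles detected: {len(d.cycle_bounds)}")
    print(f"mean cycle period: {d.cycle_periods.mean() * 1000:.1f} ms")
    print(f"arithmetic reconstruction R^2: {r2:.4f}")
    for name, series in [("midpoint", d.midpoint), ("amplitude", d.amplitude), ("phase", np.sin(d.phase))]:
        label, _, _ = classify_feature_speed(series, d.rate)
        print(f"feature {name}: {label}")

    step = 10  # 50-Hz summary keeps the table small
    out = pd.DataFrame(
        {
            "time_s": np.arange(len(d.angle))[::step] / d.rate,
            "angle": d.angle[::step],
            "midpoint": d.midpoint[::step],
            "amplitude": d.amplitude[::step],
            "phase": d.phase[::step],
            "reconstructed": theta_hat[::step],
        }
    )
    path = os.path.join(args.out, "decomposition.csv")
    out.round(4).to_csv(path, index=False)
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
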