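#!/usr/bin/env python
"""Decode whisker position (15-ms bins, 11-bin window) and locomotion speed
(100-ms bins, 9-bin window) from population spike counts with lagged ridge
regression; includes the circular-shift shuffle control and a
neuron-subsampling performance curve.
"""

import argparse
import json
import os

import numpy as np
import pandas as pd

from whiskenc.decoding import DecoderConfig, decode_session, shuffle_control, subsample_curve
from whiskenc.session import bin_session, read_session


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results")
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    session = read_session(os.path.join(args.out, "session.h5"))
    alphas = np.logspace(-1, 5, 7)

    b15 = bin_session(session, 0.015)
    cfg_pos = DecoderConfig(alphas=alphas, seed=args.seed)
    pos = decode_session(b15, cfg_pos)
    shuf = shuffle_control(b15, cfg_pos, seed=args.seed)
    sizes = [s for s in (5, 10, 20, len(session.spikes)) if s <= len(session.spikes)]
    curve = subsample_curve(b15, cfg_pos, sizes, n_repeats=5)

    b100 = bin_session(session, 0.100)
    speed = decode_session(b100, DecoderConfig.for_speed(alphas=alphas, seed=args.seed))

    print(f"whisker position:  held-out R^2 = {pos.r2:.3f} (shuffle control {shuf.r2:.3f})")
    print(f"locomotion speed:  held-out R^2 = {speed.r2:.3f}")
    for c in curve:
        if not c["skipped"]:
            print(f"  {c['size']:3d} units -> R^2 {c['mean']:.3f} ± {c['sd']:.3f}")

    metrics = {
        "position_r2": pos.r2,
        "position_shuffle_r2": shuf.r2,
        "speed_r2": speed.r2,
        "subsample": [{k: v for k, v in c.items() if k != "r2s"} for c in curve],
    }
    with open(os.path.join(args.out, "decoding_metrics.json"), "w") as fh:
        json.dump(metrics, fh, indent=2)
    pd.DataFrame({"actual": pos.actual, "predicted": pos.predicted}).to_csv(
        os.path.join(args.out, "position_decoding_trace.csv"), index=False
    )
    print(f"wrote {args.out}/decoding_metrics.json and position_decoding_trace.csv")


if __name__ == "__main__":
    main()
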