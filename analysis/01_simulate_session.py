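#!/usr/bin/env python
"""Simulate a recording session: whisking/locomotion kinematics plus a
Poisson-spiking population with known ground-truth tuning.

Writes the session (HDF5) and the ground-truth tuning table (CSV) under
--out.  Later drivers consume these files.
"""

import argparse
import os

from whiskenc.session import write_session
from whiskenc.synth import KinematicsSpec, PopulationSpec, generate_population


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--duration", type=float, default=300.0)
    ap.add_argument("--n-neurons", type=int, default=24)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()
    os.makedirs(args.out, exist_ok=True)

    kspec = KinematicsSpec(duration=args.duration, seed=args.seed)
    pspec = PopulationSpec(n_neurons=args.n_neurons, fraction_phase_tuned=0.5, seed=args.seed)
    session, truth, _ = generate_population(pspec, kspec)

    sess_path = os.path.join(args.out, "session.h5")
    truth_path = os.path.join(args.out, "ground_truth.csv")
    write_session(session, sess_path)
    truth.to_csv(truth_path, index=False)

    n_spikes = sum(len(s) for s in session.spikes)
    print(f"session: {args.duration:.0f} s, {args.n_neurons} units, {n_spikes} spikes")
    print(f"mean whisk period: {session.meta['gt_mean_period'] * 1000:.1f} ms")
    print(f"locomotion: {session.speed.mean() * args.duration / 100:.0f} m")
    print(f"wrote {sess_path} and {truth_path}")


if __name__ == "__main__":
    main()
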