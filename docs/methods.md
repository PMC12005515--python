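# Methods

This note documents the models, the synthetic world, the numerical choices,
and the limits of what a green test establishes.  It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Kinematic decomposition

Whisker angle θ(t) (degrees, nominally 500 Hz) is decomposed as

    θ(t) ≈ O(t) − A(t) · (1 − cos φ(t))

* **Envelopes.**  Peaks and troughs are detected with minimum prominence 1°
  and minimum separation 20 ms (matching the 5–50 Hz whisking band) and
  Akima-interpolated to every sample; edges are held at the nearest
  extremum.  Midpoint/offset *O* is the upper envelope, amplitude *A* half
  the envelope width.  Where Akima overshoot would cross the envelopes they
  are pinched to their midpoint, preserving upper ≥ lower.
* **Phase.**  Zero-phase (forward–backward) 4th-order Butterworth band-pass
  5–50 Hz, then the angle of the analytic (Hilbert) signal.  Convention:
  φ = 0 at the most protracted point of a cycle, ±π at the most retracted.
  The alternative convention (0 = retracted) circulates in parts of the
  literature; this package's choice is fixed and is never silently
  remapped, so preferred phases must be compared within one convention.
* **Cycles.**  A protraction onset is an upward wrap of φ through −π.
  Cycles outside 20–200 ms, or with mean amplitude below 1°, are discarded:
  the analytic phase of a flat, noisy trace still wraps, but those wraps
  are not whisks.
* **Frequency F** is the per-cycle reciprocal period, held constant within
  the cycle and 0 in quiescence.  (How this feature is defined varies
  between labs; it participates in model selection but carries no other
  analysis here.)
* **Slow/fast classification** uses the lag at which the normalized
  autocorrelation first falls below 0.5: faster than one mean whisk period
  (52 ms) → fast, else slow.
* **Offset change-points** use greedy binary segmentation on within-segment
  squared residuals with a BIC-flavored default penalty
  2·σ̂²·log n (σ̂² from first differences) and a 250-ms minimum segment.

## LNP encoding model

Features (speed L, midpoint O, amplitude A, frequency F) are binned at
50 ms (circular mean for phase, arithmetic mean otherwise; half-open bins)
and one-hot coded into 20 equal-width bins spanning each feature's observed
range (top edge → last bin).  The expected count is the exponential of the
summed block weights; there is no explicit intercept — a constant rate is
absorbed by the blocks.

Fitting maximizes the Poisson log-likelihood with a smoothness penalty
β·Σ(w_{i+1} − w_i)² per block, β = 5·10⁻² by default (a conventional value
for 20-bin one-hot LNP models; 20 free bins per feature overfit at
realistic spike counts).  A tiny L2 term (10⁻⁶) pins the exact flat
direction that lets two blocks trade a constant, without which L-BFGS
wanders.  The objective is normalized per bin so tolerances are scale-free;
optimization is L-BFGS-B from zero initialization (deterministic), and a
fit that stops with a normalized gradient above 10⁻³ raises.

**Scoring.**  LLH = (negLLH_meanFR − negLLH_model)/ln 2 bits/spike, each
negLLH spike-normalized, (1/Σnₜ)Σ[r̂ₜ − nₜ log r̂ₜ + log nₜ!]; the
mean-rate model uses the training-fold mean count.  log nₜ! cancels in the
difference but is computed (log-gamma) for reported absolute values.
Folds: 10, built from contiguous 100-bin chunks dealt round-robin, so each
fold samples the whole session without fine-grained interleaving leakage.
A zero-spike test fold scores 0 and is flagged.

**Forward search** starts from the best single-feature model and grows
while the best enlarged model improves held-out LLH (one-sided Wilcoxon
signed-rank over folds, α = 0.05); ties break toward fewer features, then
the order L < O < A < F.  A neuron whose final model does not beat the
mean-rate model is unclassified.  Feature contributions follow
contrib(f) = LLH(sel ∪ {f}) − LLH((sel ∪ {f}) \ {f}) over {L, O, A},
negatives clamped to 0, normalized to sum 1 (undefined if all ≤ 0).

## Temporal models

Time-shifted models use 25-ms bins and displace the neuron's best feature
by {−200, −150, −100, −75, −50, −25, 0, 25, 50, 75, 100, 150, 200} ms
(positive = future feature predicts current spikes); edge bins without
shifted data are dropped symmetrically.  Temporal bias integrates the
baseline-subtracted curve (minimum → 0, since LLH can be negative and raw
AUC would be sign-ambiguous) by trapezoid separately over positive and
negative shifts — shift 0 belongs to neither — giving
(AUC₊ − AUC₋)/(AUC₊ + AUC₋), exactly antisymmetric under time reversal.
k-means clustering (k = 3, 50 restarts, fixed seed, Euclidean on
min-max-normalized curves) orders clusters by template bias
(past < present < future).

The temporal-kernel GLM uses 20-ms bins, lags −10…+10, standardized
features, ridge regression with the penalty chosen by 5-fold CV on the
first 80% of bins and R² reported on the final 20%.  Significance comes
from 1,000 circular shifts of the spike-count series (offset ≥ 1 s,
preserving autocorrelation — an i.i.d. shuffle would be anticonservative),
refit at the chosen penalty; p = (#null ≥ observed + 1)/(n + 1).
Preferred feature = largest Σ|coefficients| (ties flagged, order L < O < A);
preferred time = lag of the maximum coefficient within that feature.

## Phase tuning

Analysis is restricted to whisking epochs (amplitude ≥ 2.5°, configurable)
because phase is meaningless in quiescence.  Spike phases are read off the
phase trace at the nearest sample.  Rates are spike counts divided by
occupancy time in each of 12 30° bins.  The Rayleigh test applies to the
spike-phase sample (one angle per spike, exact small-sample-corrected
approximation p = exp(√(1 + 4n + 4(n² − R²)) − (1 + 2n))), not to the
12-bin curve; the preferred phase is the circular mean of spike phases.
Curves with < 50 spikes are flagged and tests suppressed.

## Decoding

Whisker position: 15-ms bins, 11-bin window (5 before, 1 concurrent, 5
after = 165 ms; a "175 ms" figure also circulates for this window, the
11 × 15 ms construction is what is implemented).  Locomotion speed: 100-ms
bins, 9-bin centered window (the centered split is a choice; a causal
window is equally consistent with T = 9).  Ridge penalty by 10-fold CV on
the first 80% of rows over a log-spaced grid; R² on the contiguous final
20% — train and test never interleave, and R² may be negative.  The shuffle
control circularly shifts each unit's counts independently (≥ 5 s) and must
collapse performance, since kinematics are untouched.

## The synthetic world

`generate_kinematics` states one behavioral world and the tests live in it:

* whisk-cycle periods drawn per cycle from a gamma law (shape 25) with mean
  52 ms, clipped to the 5–25 Hz band; φ advances linearly within a cycle;
* midpoint and amplitude are bounded OU processes (midpoint 20 ± 4°, τ 2 s,
  range 8–32°; amplitude 9 ± 3°, τ 1.5 s, range 2.5–18° while whisking,
  0.5° in quiescence), chosen as typical of free whisking in air;
* bout structure calibrated so a 600-s session contains ≈ 5–6 × 10³ whisk
  cycles and ≈ 80–110 m of locomotion over a wide speed range — the
  per-session totals reported for this preparation;
* the `coupling` knob (default 0.6) both mixes a smoothed-speed latent into
  the envelope anomalies and sets the probability that a locomotion bout is
  accompanied by whisking, so the realized speed–amplitude correlation
  tracks the knob (≈ 0.45 at 0.5, ≈ 0 at 0), reproducing the reported
  co-variation of locomotion speed with the whisking envelopes;
* angle gets 0.2° of white measurement noise (tracking jitter).

Neurons are simulated at 5-ms resolution from the *ground-truth* features
through exactly the exponential one-hot rate model the encoder estimates,
times a 12-bin phase multiplier normalized to mean 1 (so phase tuning does
not move the mean rate and slow-feature recovery separates cleanly);
baselines are calibrated so each unit hits a target mean rate (drawn
5–30 Hz).  Counts are scattered uniformly within bins into spike times, so
any later binning is consistent.  Population defaults mirror the reported
mix: 59% single-feature, 41% multi-feature (per-feature weight span scaled
by 1/√k to keep multi-feature units physiological), and about half of
phase-tuned units carry a slow-feature gain.

**What a green test does not establish.**  The generator's angle is built
from the same functional form the decomposition inverts, its neurons from
the same rate model the GLM estimates.  Green recovery tests therefore
validate the *estimators and their calibration*, not the biological
adequacy of the models; real sessions bring tracking dropouts, non-Poisson
dispersion, history dependence, and envelope statistics this world does not
emulate.

## Known limitation: the position-decoding level (t1)

With 40 simulated units at 5–30 Hz mean rates, held-out position-decoding
R² on this synthetic world is ≈ 0.78–0.83, not the ≈ 0.92 of the original
simulation that used real-session kinematics (unpublished) and tuning
curves whose rate scale is not reported.  Two measured facts locate the
gap: (i) with phase-only phase units the *noiseless* linear ceiling is
≈ 0.91 because a linear readout cannot represent the amplitude × cos φ
product — which is why the population here gives half the phase units an
amplitude/midpoint gain (as roughly half of real phase-tuned units have),
raising the noiseless ceiling to ≈ 0.99; (ii) the remainder is spike-count
noise: doubling all rates gives R² ≈ 0.86, quadrupling ≈ 0.91.  The
decoder itself is validated separately (realizable targets R² ≥ 0.999;
shuffle controls ≤ 0.05).  The simulated rates were not raised to chase
the target.

## Trim (reafference) comparison

Planted trim effects: *lost* units are flattened (they keep firing at the
scaled mean rate but lose tuning), *gained* units are untuned pre with a
latent tuned spec revealed post, *modified* units have their tuning curves
rolled 5 bins **and** halved in span — a pure shift would leave the refit
model's predictability unchanged and be undetectable by a
performance-based test — and all post rates are scaled by 0.8.  The
classifier refits forward search per condition on range-matched bins
(intersection of feature ranges); tuned-both units are compared by a
two-sample t-test over fold LLHs, with "modified" additionally requiring
that the pre/post tuning curves are no longer positively correlated: fold
LLHs are not independent samples, and the t-test alone is anticonservative
across sessions with different behavior.  Occupancy matching down-samples
both conditions per joint 20 × 20 position × speed bin to the minimum
occupancy (seeded), leaving bin-wise differences of exactly zero.
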