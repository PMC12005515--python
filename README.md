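# whiskenc

Encoding and decoding of self-motion — whisking kinematics and locomotion
speed — in spiking neural populations, built for the kind of experiment
where a head-fixed mouse whisks and runs freely while a population of
neurons (e.g., in superior colliculus) is recorded at millisecond
resolution.

The package answers, on data with known ground truth, the questions such a
recording raises:

* **Which kinematic features does each neuron encode?**  Whisker angle
  θ(t) is decomposed into slow features — midpoint/offset *O* (upper
  envelope bound), amplitude *A* (half envelope width) — and the fast
  feature phase *φ* (analytic signal of the 5–50 Hz band-passed trace),
  plus locomotion speed *L* and whisking frequency *F*.  Each neuron is fit
  with a linear-nonlinear Poisson (LNP) GLM over one-hot-binned features,

  &nbsp;&nbsp;&nbsp;&nbsp; E[nₜ] = exp( Σ_f X_fᵗ · W_f ),

  scored by cross-validated log-likelihood relative to the mean-rate model
  in bits/spike, LLH = (negLLH_meanFR − negLLH_model)/ln 2, and the encoded
  feature set is chosen by greedy forward search (one-sided Wilcoxon
  signed-rank over 10 folds, α = 0.05; unclassified if nothing beats the
  mean-rate model).
* **When?**  Time-shifted LNP models over shifts {−200 … +200} ms give a
  temporal curve per neuron; its normalized future-vs-past AUC difference
  (temporal bias ∈ [−1, 1]) and preferred shift separate past-, present-,
  and future-encoding units, corroborated by a ±10-lag ridge kernel GLM
  with a circular-shift permutation null.
* **Phase tuning.**  Occupancy-normalized 12-bin (30°) phase curves,
  Rayleigh test, circular-mean preferred phase, modulation depth
  (maxFR − minFR)/meanFR.
* **Can the population reconstruct behavior?**  Lagged ridge decoding of
  whisker position (15-ms bins, 11-bin window) and locomotion speed
  (100-ms bins, 9-bin window), with shuffle controls and neuron-subsampling
  curves.
* **What does reafference contribute?**  Pre/post whisker-trim comparison:
  range-matched refits, lost/gained/modified/no-change categories, and
  occupancy-matched firing-rate tests (2D position × speed down-sampling,
  Wilcoxon signed-rank).

Because raw recordings of this kind are rarely shared, the package includes
a first-class synthetic-data module (`whiskenc.synth`): whisking with a
~52-ms mean cycle period, drifting midpoint/amplitude envelopes,
bout-structured locomotion coupled to the whisking envelopes, and Poisson
populations with known tuning — every analysis here is exercised against
that ground truth.

## Worked example

The `analysis/` drivers run the full pipeline on a simulated session and
write tables under `results/` (or any `--out`):

```bash
python analysis/01_simulate_session.py --seed 1 --duration 240 --n-neurons 16 --out results
python analysis/02_decompose_whisking.py --out results
python analysis/03_fit_encoding_models.py --out results
python analysis/04_temporal_models.py --out results
python analysis/05_phase_tuning.py --out results
python analysis/06_decode_position_speed.py --out results
python analysis/07_trim_comparison.py --seed 1 --duration 240 --n-neurons 12 --out results
```

Step 01/02 output for seed 1:

```
session: 240 s, 16 units, 75445 spikes
mean whisk period: 52.2 ms
whisk cycles detected: 3237
arithmetic reconstruction R^2: 0.9975
feature midpoint: slow
feature amplitude: slow
feature phase: fast
```

The 52-ms cycle period and the slow/fast split are the generator's stated
world; the reconstruction R² says the decomposition
θ̂ = O − A·(1 − cos φ) loses almost nothing.  Step 03 then recovers the
true encoded feature set of 14/16 units exactly (88%; the two misses are
weakly tuned 3-feature units where one feature does not reach
significance), step 05 recovers every planted preferred phase to within a
few degrees (e.g. unit u001: true 91.3°, estimated 93.2°, Rayleigh
p ≈ 0), and step 07 recovers all twelve planted trim labels, with the
matched-occupancy rate test detecting the planted 20% rate reduction
(Wilcoxon p = 4.9 × 10⁻⁴, direction "decrease").  Step 06 on this small
generic population decodes locomotion speed with R² = 0.93 and position
with R² = 0.38 (position decoding needs the larger dedicated mixed
population used in the acceptance run, not 16 generic units).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, (t1) the held-out R² for decoding whisker
position from a 600-s simulated population of 40 neurons (20 slow-tuned,
20 phase-tuned) with the 15-ms/11-bin lagged ridge decoder, and (t2) the
R² of the arithmetic angle reconstruction on a 600-s synthetic trace, and
writes both to the JSON file given by `--out`.  See `docs/methods.md` for
what these quantities do and do not establish on synthetic data.
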