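# optodetect

Analysis pipeline for all-optical detection experiments, in which ensembles
of cortical neurons are photostimulated while behaviour (licking) and
population calcium activity are recorded. The package covers the full
analysis path from raw per-session data to psychometric inference:

- **behavior** — go/catch trial scoring in a 0.15–1.15 s response window,
  auto-reward handling, reaction-time exclusions, sated-animal session
  truncation, P(response) and d′.
- **traces** — neuropil subtraction (robust-regression coefficient bounded
  to [0.5, 1], 33rd-percentile re-baselining), a 5-volume peri-stimulus
  artefact-exclusion epoch, and trial-wise ΔF/σF response extraction.
- **thresholds** — per-neuron activation/suppression thresholds from
  correct-reject catch-trial response distributions, with session-wide SD
  scaling factors calibrated to a 5% held-out false-positive rate
  (scaling-factor sweep 1–3, permuted 80:20 train:test splits, cubic
  interpolation).
- **targets** — 3D target-zone classification (10 µm lateral radius, full
  axial extent), activated-target counts, network activation/suppression
  proportions and OLS trends.
- **matching** — hit:miss-balanced resampling (50:50 lick:no-lick per trial
  type) to remove lick contamination from network metrics.
- **psychometrics** — log-normal psychometric functions
  ψ(x) = γ + (1−λ−γ)·Φ(C(log x − m)/w) with fixed lapse/guess rates,
  weighted binomial ML fitting, 10/50/90% curve points, midpoint slope,
  and permutation cross-validated prediction of P(lick) from neural
  predictors.
- **lick_analysis** — Gaussian-smoothed lick traces, per-neuron lick
  correlations, spontaneous lick-bout detection.
- **synthetic_data** — a seeded session simulator (trial sequences with
  exact type ratios and a 3-trial run-length limit, licking drawn from a
  ground-truth psychometric curve, calcium-like traces with planted target
  activations, ensemble-size-scaled background suppression and
  lick-coupled neurons) with full ground-truth bookkeeping so every stage
  is testable by parameter recovery.
- **pipeline** — glue composing the above: session → matched per-type
  network datapoints.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance checks
(false-positive calibration accuracy, matching exactness, sequence
constraints, psychometric identities, parameter recovery, planted-signal
cross-validation, suppression-slope recovery, classification oracles).

## CLI

```bash
optodetect simulate --config cfg.yaml --seed 1 --out session_dir/
optodetect score --trials session_dir/trials.csv --out summary.json
optodetect calibrate --responses resp.h5 --kind activation --nperm 1000 --seed 7 --out thr.json
optodetect fit --data points.csv --fix-lambda auto --fix-gamma 0.1 --out fit.json
optodetect predict --data points.csv --nperm 1000 --seed 7
```

A session bundle is a directory of plain formats: `trials.csv` (trial
table with semicolon-joined lick times), `targets.csv` (photostimulation
coordinates per trial type), `traces.h5` (ROI + neuropil fluorescence,
centroids, volume times) and, for simulated sessions,
`ground_truth.json`.
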