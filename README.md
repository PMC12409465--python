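# kmipd

Reconstruct individual patient data (IPD) from digitized Kaplan–Meier
survival curves and published numbers at risk.

Randomized trials with time-to-event outcomes publish KM curves, hazard
ratios and at-risk tables — but almost never the per-patient records
behind them. Meta-analysts, trial designers and methods researchers who
need IPD can recover a close approximation from the published figure:
digitize the curve into (time, survival) coordinates, then invert the
product-limit construction against the reported numbers at risk. `kmipd`
implements that pipeline end to end, together with the agreement metrics
used to judge the result and a synthetic trial simulator that validates
the whole loop against known ground truth.

## What it does

- **Preprocessing** — raw digitizer clicks are anchored at (0, 1),
  time-sorted, clamped into [0, 1], forced monotone non-increasing and
  deduplicated, with a report of every adjustment.
- **Reconstruction** — a Guyot-type iterative algorithm. With clicks
  (tᵢ, Sᵢ) partitioned by the at-risk times t₁ < … < t_K into intervals
  [t_k, t_{k+1}), an inner loop chooses the interval censor count c_k so
  the running at-risk estimate matches the published n_{k+1}; censoring
  times are spread evenly across the interval and events at each click
  are recovered by inverting the KM ratio,

  d_i = round( n̂ᵢ · (1 − Sᵢ / S*ᵢ) ),

  where n̂ᵢ is the running at-risk estimate and S*ᵢ the running KM value
  at the last event click. The output is one record (time, event, arm)
  per patient.
- **Survival statistics** — product-limit estimates, two-arm Cox
  proportional-hazards HR with 95% CI (Efron ties, via lifelines), and
  milestone/quantile survival with Greenwood log(−log) bands.
- **Agreement metrics** — |HR_r − HR_o| / HR_o × 100 (%) and the
  percentage of the original CI not covered by the reconstructed one,
  plus RMSE / mean / max absolute error and a KS comparison between the
  fitted step function and the read-in coordinates.
- **Simulation** — exponential, Weibull and piecewise-exponential trial
  generators (delayed effects, crossing hazards), a virtual digitizer
  (click subsampling, coordinate jitter, tilted verticals), and a
  replicated benchmark harness with preprocessing / at-risk ablations.

## Worked example

`examples/02_reconstruct_trial.py` simulates a 200-patients-per-arm
trial with true HR 0.7, digitizes each arm's KM curve with realistic
noise (60% of clicks kept, coordinate jitter, tilted step verticals),
reconstructs the IPD and refits the Cox model:

```
arm 0: 200 records reconstructed (141 events), curve RMSE 0.0020, converged: True
arm 1: 200 records reconstructed (121 events), curve RMSE 0.0025, converged: True

HR on source data:        0.685 (0.537-0.874)
HR on reconstructed data: 0.693 (0.543-0.884)
absolute HR difference:   1.13%
CI non-overlap:           1.79%
```

The reconstructed records reproduce every published at-risk count, the
refitted HR differs from the source-data HR by about 1%, and the CIs
almost coincide — the reconstructed data would support the same
inference as the source trial. The other examples cover click
preprocessing (`01`), milestone survival (`03`) and the replicated
benchmark with ablations (`04`).

## Command line

A thin CLI wraps the same functions for batch work:

```sh
kmipd preprocess  --in raw.csv --out clean.csv --report report.json
kmipd reconstruct --config run.yaml --out ipd.csv --report report.json
kmipd analyze     --ipd ipd.csv --out analysis.json
kmipd evaluate    --reconstructed analysis.json --original orig.json --out metrics.json
kmipd simulate    --scenario scenario.yaml --out-dir sim/
kmipd benchmark   --scenario scenario.yaml --reps 20 --seed 7 --out summary.json
```

`run.yaml` lists one coordinate CSV per arm plus its at-risk table and
optional totals; see `tests/test_cli.py` for a complete example.

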