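"""Benchmark the pipeline over replicated noisy digitizations and show
why preprocessing and numbers at risk matter.

Each replicate simulates a fresh trial, corrupts its KM step corners
the way a digitizer would, reconstructs both arms and compares the
Cox HR against the one fitted on the source data. The two ablations
skip coordinate preprocessing or withhold the at-risk table (keeping
only the baseline count).
"""

from kmipd import DigitizerNoise, default_scenario, evaluate_scenario

scenario = default_scenario()
noise = DigitizerNoise()  # keep 60% of clicks, jitter, tilted steps
REPS, SEED = 15, 42

full = evaluate_scenario(scenario, noise, n_reps=REPS, seed=SEED)
no_prep = evaluate_scenario(
    scenario, noise, n_reps=REPS, seed=SEED, apply_preprocess=False
)
no_atrisk = evaluate_scenario(scenario, noise, n_reps=REPS, seed=SEED, use_atrisk=False)

print(f"mean |dHR| over {REPS} paired replicates (200/arm, true HR 0.7):")
print(f"  full pipeline:          {full.summary['hr_diff_mean']:.2f}%")
print(f"  without preprocessing:  {no_prep.summary['hr_diff_mean']:.2f}%")
print(f"  without at-risk table:  {no_atrisk.summary['hr_diff_mean']:.2f}%")
print(f"\nmean CI non-overlap, full pipeline: {full.summary['nonoverlap_mean']:.2f}%")
print(
    f"replicates with |dHR| < 5%: {full.summary['n_lt_5']}/{REPS}, "
    f"5-10%: {full.summary['n_5_to_10']}, >=10%: {full.summary['n_ge_10']}"
)
print(
    "\nBoth ablations should show larger mean discrepancies: coordinate "
    "adjustment and at-risk anchoring each carry real information."
)
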