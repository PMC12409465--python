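"""Full round trip: simulate a trial, digitize its KM curves virtually,
reconstruct per-patient data and compare hazard ratios.

The simulated truth plays the role of the (normally inaccessible)
original patient data, so the agreement metrics quantify exactly how
much the digitize-and-reconstruct pipeline loses.
"""

import numpy as np

from kmipd import (
    DigitizerNoise,
    IPDataset,
    abs_hr_pct_diff,
    ci_nonoverlap_pct,
    cox_hr,
    default_scenario,
    preprocess_curve,
    reconstruct_arm,
    render_digitized,
    simulate_trial,
)

scenario = default_scenario(seed=7)  # 200/arm, true HR 0.7, 36u follow-up
truth = simulate_trial(scenario)
hr_true = cox_hr(truth)

noise = DigitizerNoise(seed=7)  # subsampled clicks, jitter, tilted steps
atrisk_times = np.arange(0.0, 36.1, 4.5)  # published every followup/8

arms = []
for a in (0, 1):
    arm_truth = truth.select_arm(a)
    raw, at_risk, totals = render_digitized(arm_truth, noise, atrisk_times)
    curve, _ = preprocess_curve(raw)
    result = reconstruct_arm(curve, at_risk, totals)
    print(
        f"arm {a}: {len(result.ipd)} records reconstructed "
        f"({result.ipd.n_events} events), curve RMSE "
        f"{result.fit_stats['rmse']:.4f}, converged: {result.converged}"
    )
    arms.append(
        IPDataset(result.ipd.time, result.ipd.event, np.full(len(result.ipd), a, int))
    )

hr_rec = cox_hr(IPDataset.concat(arms))
print(f"\nHR on source data:        {hr_true.hr:.3f} ({hr_true.lo:.3f}-{hr_true.up:.3f})")
print(f"HR on reconstructed data: {hr_rec.hr:.3f} ({hr_rec.lo:.3f}-{hr_rec.up:.3f})")
print(f"absolute HR difference:   {abs_hr_pct_diff(hr_rec.hr, hr_true.hr):.2f}%")
print(f"CI non-overlap:           {ci_nonoverlap_pct(hr_true.ci, hr_rec.ci):.2f}%")
print(
    "\nSmall percentages mean the reconstructed data would support the "
    "same inference as the source trial."
)
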