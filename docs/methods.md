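# Methods

## Problem and model

A published Kaplan–Meier figure encodes, up to digitization error, the
product-limit estimate of a trial arm's survival function together with
an at-risk table (counts n_k of patients still under follow-up at times
t_k) and sometimes the arm totals (patients randomized N, events D).
`kmipd` inverts this encoding: from digitized curve coordinates and the
at-risk table it produces per-patient records (time, event indicator,
arm) whose KM estimate reproduces the published curve and whose at-risk
bookkeeping reproduces the published counts.

The reconstruction cannot recover information the figure does not
carry: individual censoring times within an at-risk interval, covariates
and stratification variables are gone. Reconstructed IPD is an
approximation suited to secondary analyses of the group effect, not a
substitute for the original records.

## Preprocessing

Raw digitizer output violates the defining properties of a survival
curve. The adjustment pipeline applies, in order: a stable sort by
time; a hard clamp of survival into [0, 1]; anchoring at (0, 1) —
negative-time clicks are absorbed into the anchor, a first click at
t = 0 with S ≠ 1 is set to (0, 1), and a positive first click time gets
an explicit (0, 1) point prepended so the observed click survives; a
forward monotone pass replacing any survival value above its
predecessor with that predecessor; and removal of exact consecutive
duplicates. The operation is idempotent and deterministic; every action
is counted in a report. Clamping precedes the monotone pass so jitter
above 1 cannot leak through the anchor. When two clicks share a time,
both are kept and the monotone pass pulls the later one down (the
resulting exact duplicate is then dropped); the tie is flagged in the
report. No smoothing or resampling is done — clicks are evidence, not a
curve model.

## Reconstruction

Clicks are partitioned by the at-risk times into half-open intervals
[t_k, t_{k+1}) (boundary clicks belong to the later interval, matching
"at risk at time t" semantics); the last bin closes at the final click.
Within interval k, given the running at-risk estimate and the running
KM value S\* at the last event click, a candidate censor count c_k
places censoring times evenly at t_k + j·(t_{k+1} − t_k)/(c_k + 1),
j = 1..c_k — endpoints excluded — and the clicks are walked in order:
at click i the event count is d_i = round(n̂_i (1 − S_i/S\*)), rounded
half-up and clamped to [0, n̂_i]; S\* updates only when d_i > 0. The
inner loop starts from c_k = 0, adds the residual (estimated minus
published at-risk at t_{k+1}) after each pass, and stops on residual
zero, a repeated candidate, or 25 passes, keeping the
minimal-|residual| candidate with ties broken toward smaller c_k. A
residual that cannot reach zero marks the interval non-converged; the
solution and residual are reported rather than silently adjusted.

The final interval has no at-risk anchor. If D is published, the event
deficit relative to the running total is distributed over the final
interval's clicks proportionally to their survival drops
(largest-remainder rounding, clamped by the running at-risk); otherwise
zero censoring is assumed strictly inside the interval. Survivors after
the last click are censored there, so the arm always conserves its
initial count (N when provided, else n_1).

Half-up rounding and the S\*-update rule are fixed so that exact step
coordinates with an at-risk entry at every event time and true totals
round-trip exactly — this is tested against the source data as oracle.
Reconstruction is fully deterministic. A raw (unpreprocessed) curve is
accepted for sensitivity analyses; negative click times then clamp to
zero in the output records, since follow-up cannot be negative.

With only a baseline count (no interior at-risk entries) the algorithm
still runs but assumes no censoring before the last click; a prominent
warning marks this mode as unreliable, and the benchmark ablation
quantifies how much it loses.

## Survival statistics

The product-limit fit and the two-arm Cox model are delegated to
lifelines; `kmipd` keeps its own integer bookkeeping (n_risk, n_event,
n_censor per event time) derived from the fit's event table, and tests
cross-check it against a brute-force product-limit loop.
The Cox fit uses the Efron tie correction — reconstruction rounds
events onto shared click times, so ties are heavy by construction — and
a 95% Wald CI on the log scale. Milestone machinery follows the
standard quantile convention, q-quantile time = inf{t : S(t) ≤ 1 − q},
with confidence bounds from inverting pointwise log(−log) Greenwood
bands; the same bands give survival-at-fixed-time CIs. The log(−log)
transform is a documented choice, not asserted to match any particular
prior implementation. A quantile the curve never reaches is reported as
NaN (not reached); an all-censored arm has S ≡ 1 and no event times.

## Agreement and accuracy metrics

Agreement of a reconstructed fit (HR_r, [L_r, U_r]) with an original
(HR_o, [L_o, U_o]):

- absolute percentage HR difference |HR_r − HR_o| / HR_o × 100;
- CI non-overlap (1 − max(0, min(U_o,U_r) − max(L_o,L_r)) / (U_o − L_o))
  × 100, clipped into [0, 100] as a guard.

Both are normalized by the original quantity and deliberately
asymmetric. Curve fidelity metrics (RMSE, mean and maximum absolute
error) evaluate the fitted KM step function right-continuously at every
click time and compare with the read-in survival values; the
Kolmogorov–Smirnov entry is a two-sample test between the two
survival-probability vectors on the click grid — a deterministic,
testable construction, documented as this package's choice. Note that
at a pre-drop step corner the right-continuous evaluation differs from
the click by the drop size, so even an exact reconstruction of a small
trial shows nonzero RMSE of order 1/N; fidelity thresholds are
therefore stated for realistic arm sizes (N ≈ 200).

## Simulator and virtual digitizer

`simulate_trial` draws per-arm event times from exponential, Weibull or
piecewise-exponential hazards (the latter realize delayed, diminishing
and crossing effects), with censoring the minimum of exponential loss
to follow-up, an administrative cut-off and end of follow-up. The
benchmark default — chosen once as a realistic mid-size oncology trial
and not revisited — is 200 patients/arm, control hazard ln2/12 per time
unit (median 12), proportional treatment effect HR 0.7, follow-up and
administrative censoring at 36 units, and loss-to-follow-up rate 0.02
(≈ 25% of control-arm observations censored overall).

`render_digitized` emits both corner points of every KM step plus the
end-of-follow-up point, then corrupts them: Bernoulli click thinning
(keep probability 0.6 by default; the first and last points always
survive), Gaussian jitter on survival (sd 0.005) and time (sd 0.1, a
click's worth of error on a 36-unit axis), and optional tilting that
offsets each post-drop corner by under 0.001 time units (capped at 40%
of the gap to the next corner so click order is preserved). These
defaults are declared conventions for the harness, not measurements of
any particular digitizer. Censoring marks are not rendered because the
reconstruction ignores them. At-risk counts and totals are computed
exactly from the source records, so digitization error is confined to
the curve itself, which is how published figures behave.

What the simulator does not emulate: image resolution limits,
overlapping curves from multiple arms on one plot, censoring-symbol
interference, and axis-calibration error. Passing benchmarks therefore
demonstrate correctness of the reconstruction given coordinates of the
stated quality, not the difficulty of extracting coordinates from hard
figures.

`evaluate_scenario` replicates simulate → digitize → preprocess →
reconstruct → Cox, comparing against the Cox fit on the source data,
and summarizes the two agreement metrics (mean, SD, median, range, and
<5% / 5–10% / ≥10% bins). All randomness flows through a seed sequence:
identical seeds give bit-identical summaries. Replicate-level failures
are counted, not fatal. Ablation flags disable preprocessing or
withhold the at-risk table; both should and do worsen mean agreement.

## Numerical and interface choices

- Time is unitless; curve, at-risk table and follow-up must share a
  scale. Unicode minus signs are accepted in coordinate files because
  figure extractions contain them.
- Test and benchmark problem sizes (200/arm; 100 replicates for
  parameter recovery, 500 for CI coverage, 15 per ablation arm) were
  chosen to give stable means at interactive runtimes.
- The loader never reorders or deduplicates raw points; preprocessing
  owns every adjustment, so raw files round-trip bit-faithfully to
  6-decimal precision.
- At-risk entries beyond the last click are dropped with a warning;
  published counts inconsistent with any monotone curve yield a
  minimal-residual, non-converged solution rather than a guess.

## Known limitations

- Stratified or covariate-adjusted published HRs cannot be reproduced;
  the Cox model here has the group indicator as its only covariate.
- Censoring times are placed evenly within intervals; analyses
  sensitive to the censoring-time distribution (not just its counts)
  should not rely on reconstructed IPD.
- Multi-arm figures are handled as separate two-arm comparisons.
- The no-at-risk mode exists for completeness and sensitivity work;
  its output should not be used for inference.
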