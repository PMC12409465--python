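"""Iterative reconstruction of individual patient data from a
preprocessed Kaplan-Meier curve and the published numbers at risk.

The algorithm inverts the product-limit recursion interval by interval.
The at-risk times t_1 < t_2 < ... < t_K partition the clicks into
half-open intervals [t_k, t_{k+1}); within interval k an inner loop
chooses the number of censored patients c_k so that the running at-risk
estimate at t_{k+1} matches the published count n_{k+1}:

* censoring times are spread evenly across the open interval,
  at t_k + j (t_{k+1} - t_k) / (c_k + 1) for j = 1..c_k — published
  curves carry no usable censoring-time information beyond the at-risk
  counts, so an even spread is the deterministic, assumption-light
  choice;
* the number of events at click i is recovered by inverting the KM
  ratio, d_i = round(n^_i (1 - S_i / S*_i)), where n^_i is the running
  at-risk estimate just before the click and S*_i the running KM value
  at the last event click (half-up rounding, fixed so that exact step
  coordinates round-trip exactly);
* the inner loop starts at c_k = 0, adds the residual
  (estimated - published at-risk at t_{k+1}) each pass, and stops at
  residual 0 or after 25 passes, keeping the minimal-|residual|
  candidate (ties broken toward fewer censorings).

After the last at-risk time there is no anchor to match. If the total
number of events is published, the event deficit is distributed over
the final-interval clicks proportionally to their survival drops;
otherwise no censoring is assumed strictly inside the final interval.
Patients still at risk after the last click are censored there, so
every reconstructed arm conserves its initial at-risk count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .survstats import km_estimate
from .types import ArmTotals, AtRiskTable, DigitizedCurve, IPDataset, KMEstimate

__all__ = [
    "IntervalSolution",
    "ReconstructionResult",
    "split_intervals",
    "reconstruct_arm",
]

MAX_INNER_ITER = 25


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class IntervalSolution:
    """Solved allocation for one at-risk interval."""

    k: int
    c_k: int
    d_i: np.ndarray
    nhat_i: np.ndarray
    converged: bool
    residual: int


@dataclass
class ReconstructionResult:
    ipd: IPDataset
    solutions: list[IntervalSolution]
    km_of_ipd: KMEstimate
    fit_stats: dict[str, float]
    warnings: list[str] = field(default_factory=list)

    @property
    def converged(self) -> bool:
        return all(s.converged for s in self.solutions)


def split_intervals(
    curve: DigitizedCurve, atrisk: AtRiskTable
) -> tuple[list[np.ndarray], AtRiskTable]:
    """Partition click indices into at-risk interval bins.

    Bins are half-open [t_k, t_{k+1}) — a click exactly on a boundary
    belongs to the later interval, matching the "at risk at time t"
    semantics — and the last bin is closed at the final click time.
    Clicks before the first at-risk time (possible for off-label raw
    input) fall into the first bin. At-risk entries beyond the last
    click are dropped with a warning: there is no curve to match there.
    """
    t_clicks = curve.times
    t_max = float(t_clicks.max())
    keep = atrisk.times <= t_max + 1e-9
    if not keep.all():
        dropped = atrisk.times[~keep].tolist()
        warnings.warn(
            f"at-risk time(s) {dropped} lie beyond the last click time "
            f"{t_max:g}; dropping those entries",
            stacklevel=2,
        )
        atrisk = AtRiskTable(atrisk.times[keep], atrisk.counts[keep])
    bounds = atrisk.times
    bins: list[np.ndarray] = []
    for k in range(len(bounds)):
        if k + 1 < len(bounds):
            mask = (t_clicks < bounds[k + 1]) & (
                (t_clicks >= bounds[k]) if k > 0 else np.ones_like(t_clicks, bool)
            )
        else:
            mask = t_clicks >= bounds[k]
        bins.append(np.flatnonzero(mask))
    return bins, atrisk


def _solve_interval(
    idx: np.ndarray,
    t: np.ndarray,
    s: np.ndarray,
    n_start: int,
    s_star: float,
    c_k: int,
    t_lo: float,
    t_hi: float,
) -> tuple[np.ndarray, np.ndarray, float, int, np.ndarray]:
    """One inner-loop pass: allocate c_k censor times evenly, then walk
    the clicks recovering events. Returns (d_i, nhat_i, s_star_end,
    n_end, censor_times)."""
    if c_k > 0:
        j = np.arange(1, c_k + 1)
        cens_times = t_lo + j * (t_hi - t_lo) / (c_k + 1)
    else:
        cens_times = np.empty(0)
    d = np.zeros(idx.size, dtype=int)
    nhat = np.zeros(idx.size, dtype=int)
    n = n_start
    for pos, i in enumerate(idx):
        # censorings placed strictly before this click leave the risk set
        if pos > 0:
            n -= int(((cens_times >= t[idx[pos - 1]]) & (cens_times < t[i])).sum())
        else:
            n -= int((cens_times < t[i]).sum())
        n = max(n, 0)
        nhat[pos] = n
        if n > 0 and s_star > 0 and s[i] < s_star:
            di = _round_half_up(n * (1.0 - s[i] / s_star))
            di = min(max(di, 0), n)
        else:
            di = 0
        if di > 0:
            s_star = s_star * (1.0 - di / n)
        d[pos] = di
        n -= di
    if idx.size:
        n -= int((cens_times >= t[idx[-1]]).sum())
    else:
        n -= c_k
    n = max(n, 0)
    return d, nhat, s_star, n, cens_times


def reconstruct_arm(
    curve: DigitizedCurve,
    atrisk: AtRiskTable,
    totals: ArmTotals | None = None,
) -> ReconstructionResult:
    """Reconstruct one arm's per-patient records.

    ``curve`` should be preprocessed (anchored, monotone); raw curves
    are accepted for sensitivity analyses but yield degraded output.
    ``atrisk`` anchors the inner loop; a single-entry table (baseline
    count only) triggers the unreliable no-at-risk mode with a warning.
    """
    totals = totals or ArmTotals()
    msgs: list[str] = []
    if not curve.preprocessed:
        msgs.append("curve is not preprocessed; reconstruction quality degrades")
    if len(atrisk) == 1:
        msgs.append(
            "no interior at-risk counts provided: censoring inside follow-up "
            "cannot be recovered and reconstructed estimates are unreliable"
        )
    for m in msgs:
        warnings.warn(m, stacklevel=2)

    bins, atrisk = split_intervals(curve, atrisk)
    t, s = curve.times, curve.surv
    n0 = int(totals.n_total) if totals.n_total is not None else int(atrisk.counts[0])
    if totals.n_total is not None and totals.n_total != atrisk.counts[0]:
        msgs.append(
            f"n_total={totals.n_total} differs from baseline at-risk "
            f"count {atrisk.counts[0]}; using n_total"
        )

    solutions: list[IntervalSolution] = []
    event_times: list[float] = []
    censor_times: list[float] = []
    n_run = n0
    s_star = 1.0
    K = len(bins)
    for k in range(K):
        idx = bins[k]
        t_lo = float(atrisk.times[k])
        anchored = k + 1 < K
        if anchored:
            t_hi = float(atrisk.times[k + 1])
            target = int(atrisk.counts[k + 1])
            best = None
            c_k, seen = 0, set()
            converged = False
            for _ in range(MAX_INNER_ITER):
                c_k = max(c_k, 0)
                if c_k in seen:
                    break
                seen.add(c_k)
                d, nhat, s_end, n_end, ct = _solve_interval(
                    idx, t, s, n_run, s_star, c_k, t_lo, t_hi
                )
                residual = n_end - target
                cand = (abs(residual), c_k, d, nhat, s_end, n_end, ct, residual)
                if best is None or cand[:2] < best[:2]:
                    best = cand
                if residual == 0:
                    converged = True
                    break
                c_k += residual
            assert best is not None
            _, c_k, d, nhat, s_end, n_end, ct, residual = best
            if residual != 0:
                msgs.append(
                    f"interval {k}: at-risk target {target} unattainable; "
                    f"closest residual {residual} with {c_k} censorings"
                )
            sol = IntervalSolution(k, c_k, d, nhat, converged, residual)
        else:
            # final interval: no at-risk anchor to match
            d, nhat, s_end, n_end, ct = _solve_interval(
                idx, t, s, n_run, s_star, 0, t_lo, float(t.max())
            )
            if totals.d_total is not None:
                deficit = int(totals.d_total) - (len(event_times) + int(d.sum()))
                if deficit != 0:
                    d, n_end = _redistribute(d, nhat, s, idx, deficit, n_end, msgs, k)
            sol = IntervalSolution(k, 0, d, nhat, True, 0)
        solutions.append(sol)
        for pos, i in enumerate(idx):
            event_times.extend([float(t[i])] * int(d[pos]))
        censor_times.extend(np.asarray(ct, float).tolist())
        n_run = n_end
        s_star = s_end

    # survivors after the final click are administratively censored there
    t_last = float(t.max())
    censor_times.extend([t_last] * max(n_run, 0))

    # raw (unpreprocessed) curves can place clicks at negative times;
    # follow-up cannot be negative, so clamp rather than crash
    times = np.maximum(np.array(event_times + censor_times), 0.0)
    events = np.array([1] * len(event_times) + [0] * len(censor_times))
    ipd = IPDataset(times, events, np.zeros(times.size, int), provenance="reconstructed")

    km = km_estimate(ipd)
    resid = km.evaluate(t) - s
    fit_stats = {
        "rmse": float(np.sqrt(np.mean(resid**2))),
        "mean_ae": float(np.mean(np.abs(resid))),
        "max_ae": float(np.max(np.abs(resid))),
    }
    return ReconstructionResult(ipd, solutions, km, fit_stats, msgs)


def _redistribute(
    d: np.ndarray,
    nhat: np.ndarray,
    s: np.ndarray,
    idx: np.ndarray,
    deficit: int,
    n_end: int,
    msgs: list[str],
    k: int,
) -> tuple[np.ndarray, int]:
    """Spread a published-total event deficit over final-interval clicks
    proportionally to their survival drops (largest-remainder rounding)."""
    d = d.copy()
    if idx.size == 0:
        msgs.append(f"interval {k}: no clicks to absorb event deficit {deficit}")
        return d, n_end
    drops = np.maximum(-np.diff(np.concatenate(([s[idx[0]]], s[idx]))), 0.0)
    if drops.sum() <= 0:
        weights = np.ones(idx.size) / idx.size
    else:
        weights = drops / drops.sum()
    raw = weights * deficit
    add = np.floor(raw).astype(int) if deficit > 0 else np.ceil(raw).astype(int)
    rem = deficit - int(add.sum())
    order = np.argsort(-(raw - add)) if deficit > 0 else np.argsort(raw - add)
    for j in range(abs(rem)):
        add[order[j % idx.size]] += 1 if rem > 0 else -1
    new_d = np.clip(d + add, 0, nhat)
    shortfall = deficit - int((new_d - d).sum())
    if shortfall:
        msgs.append(
            f"interval {k}: could not fully absorb event deficit; {shortfall} "
            "events unplaced (published totals inconsistent with curve)"
        )
    n_end = max(n_end - int((new_d - d).sum()), 0)
    return new_d, n_end
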