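"""Survival statistics on per-patient data.

Product-limit estimation and the two-arm Cox fit are delegated to
lifelines; this module wraps them in the containers the rest of the
pipeline uses and adds the milestone/quantile machinery with
log(-log)-transformed Greenwood confidence bands.

Ties are handled with the Efron correction: reconstruction rounds
events onto shared click times, so tied event times are the norm here,
not the exception.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter

from .types import HREstimate, IPDataset, KMEstimate

__all__ = ["km_estimate", "cox_hr", "milestone_survival", "survival_at_times"]

Z95 = 1.959963984540054  # Phi^-1(0.975)


def km_estimate(ipd: IPDataset) -> KMEstimate:
    """Product-limit estimate for a single arm.

    Censored subjects at a time t remain in the risk set for events at
    that same t (the standard convention). All-censored input is valid
    and yields S(t) = 1 everywhere (no event times).
    """
    if len(ipd) == 0:
        raise ValueError("need at least one record")
    if np.unique(ipd.arm).size > 1:
        raise ValueError("km_estimate expects a single arm")
    kmf = KaplanMeierFitter()
    kmf.fit(ipd.time, ipd.event)
    tbl = kmf.event_table  # indexed by time; columns observed/censored/at_risk
    ev = tbl[tbl["observed"] > 0]
    times = ev.index.to_numpy(float)
    n_risk = ev["at_risk"].to_numpy(int)
    n_event = ev["observed"].to_numpy(int)
    n_censor = ev["censored"].to_numpy(int)
    surv = np.cumprod(1.0 - n_event / n_risk)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(
            n_risk > n_event, n_event / (n_risk * (n_risk - n_event)), np.inf
        )
    var_log = np.cumsum(terms)
    return KMEstimate(
        times=times,
        surv=surv,
        n_risk=n_risk,
        n_event=n_event,
        n_censor=n_censor,
        var_log=var_log,
        n_total=len(ipd),
    )


def cox_hr(ipd: IPDataset) -> HREstimate:
    """Hazard ratio (arm 1 vs arm 0) from a Cox proportional-hazards fit
    with the group indicator as the only covariate, Efron tie handling,
    95% Wald CI on the log scale."""
    arms = np.unique(ipd.arm)
    if arms.size != 2:
        raise ValueError(f"cox_hr needs exactly 2 arms, got {arms.size}")
    msgs: list[str] = []
    events_per_arm = [ipd.select_arm(int(a)).n_events for a in arms]
    if min(events_per_arm) == 0:
        msgs.append(
            "an arm has zero events: the partial likelihood is monotone and "
            "the CI is effectively unbounded"
        )
    df = ipd.to_frame()
    # map arm labels onto 0/1 preserving order so hr is arm[1] vs arm[0]
    df["arm"] = (df["arm"] == arms[1]).astype(int)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")
    log_hr = float(cph.params_["arm"])
    se = float(cph.standard_errors_["arm"])
    hr = float(np.exp(log_hr))
    with np.errstate(over="ignore"):  # zero-event arm: CI unbounded
        lo = float(np.exp(log_hr - Z95 * se))
        up = float(np.exp(log_hr + Z95 * se))
    return HREstimate(
        hr=hr,
        lo=lo,
        up=up,
        log_hr=log_hr,
        se_log_hr=se,
        warnings=msgs,
    )


def milestone_survival(
    km: KMEstimate, quantiles: tuple[float, ...] = (0.25, 0.5, 0.75)
) -> pd.DataFrame:
    """Quantile survival times with 95% CIs.

    The q-quantile survival time is inf{t : S(t) <= 1 - q} (q = 0.5 is
    the median). Confidence bounds invert the pointwise log(-log)
    Greenwood bands: the time where the upper (lower) band first falls
    to 1 - q is the upper (lower) bound. A quantile the curve never
    reaches is reported as NaN ("not reached").
    """
    for q in quantiles:
        if not 0.0 < q < 1.0:
            raise ValueError("quantiles must lie in (0, 1)")
    lo_band, up_band = km.confidence_bands()
    rows = []
    for q in quantiles:
        level = 1.0 - q
        rows.append(
            {
                "quantile": q,
                "time": _first_crossing(km.times, km.surv, level),
                "lo": _first_crossing(km.times, lo_band, level),
                "up": _first_crossing(km.times, up_band, level),
            }
        )
    return pd.DataFrame(rows)


def _first_crossing(times: np.ndarray, values: np.ndarray, level: float) -> float:
    hit = np.flatnonzero(values <= level + 1e-12)
    return float(times[hit[0]]) if hit.size else float("nan")


def survival_at_times(km: KMEstimate, times: np.ndarray | list[float]) -> pd.DataFrame:
    """Survival probabilities at fixed times with 95% Greenwood
    log(-log) CIs (milestone survival probabilities)."""
    t = np.asarray(times, dtype=float)
    lo_band, up_band = km.confidence_bands()
    idx = np.searchsorted(km.times, t, side="right") - 1
    surv = np.where(idx >= 0, km.surv[np.maximum(idx, 0)], 1.0)
    lo = np.where(idx >= 0, lo_band[np.maximum(idx, 0)], 1.0)
    up = np.where(idx >= 0, up_band[np.maximum(idx, 0)], 1.0)
    return pd.DataFrame({"time": t, "surv": surv, "lo": lo, "up": up})
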