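"""Synthetic two-arm trials and a virtual digitizer.

This closes the validation loop: simulate a trial with known hazards,
compute its exact KM step function, corrupt the step coordinates the
way click- and trace-based digitizers do (subsampled clicks, coordinate
jitter, tilted vertical segments), then run the full
preprocess -> reconstruct -> Cox pipeline and compare against the truth.

Hazard models cover the patterns that strain proportional-hazards
analyses of immuno-oncology trials: a constant hazard (exponential),
monotone hazards (Weibull) and piecewise-constant hazards, which
realize delayed, diminishing or crossing treatment effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .metrics import abs_hr_pct_diff, ci_nonoverlap_pct
from .preprocess import preprocess_curve
from .reconstruct import reconstruct_arm
from .survstats import cox_hr, km_estimate
from .types import ArmTotals, AtRiskTable, DigitizedCurve, IPDataset

__all__ = [
    "Exponential",
    "Weibull",
    "PiecewiseExponential",
    "SimScenario",
    "DigitizerNoise",
    "default_scenario",
    "simulate_trial",
    "render_digitized",
    "evaluate_scenario",
    "ScenarioSummary",
    "hazard_from_dict",
]


@dataclass(frozen=True)
class Exponential:
    """Constant hazard; mean survival 1/rate."""

    rate: float

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.exponential(1.0 / self.rate, size=n)


@dataclass(frozen=True)
class Weibull:
    """Weibull hazard; shape < 1 decreasing, > 1 increasing."""

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("shape and scale must be positive")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.scale * rng.weibull(self.shape, size=n)


@dataclass(frozen=True)
class PiecewiseExponential:
    """Piecewise-constant hazard: rates[j] applies on
    [breaks[j-1], breaks[j]) with breaks[-1] = infinity.

    A treatment arm sharing the control rate before a break and a lower
    rate after it realizes a delayed treatment effect; a higher-then-
    lower (or the reverse) pattern realizes crossing hazards.
    """

    breaks: tuple[float, ...]
    rates: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.rates) != len(self.breaks) + 1:
            raise ValueError("need exactly len(breaks) + 1 rates")
        if any(r <= 0 for r in self.rates):
            raise ValueError("rates must be positive")
        if any(b2 <= b1 for b1, b2 in zip(self.breaks, self.breaks[1:])) or (
            self.breaks and self.breaks[0] <= 0
        ):
            raise ValueError("breaks must be positive and strictly increasing")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        # invert the piecewise-linear cumulative hazard at Exp(1) draws
        edges = np.array((0.0,) + self.breaks)
        rates = np.array(self.rates)
        widths = np.diff(edges)
        cumhaz = np.concatenate(([0.0], np.cumsum(rates[:-1] * widths)))
        e = rng.exponential(1.0, size=n)
        seg = np.searchsorted(cumhaz, e, side="right") - 1
        return edges[seg] + (e - cumhaz[seg]) / rates[seg]


HazardModel = Exponential | Weibull | PiecewiseExponential


def hazard_from_dict(spec: dict) -> HazardModel:
    """Build a hazard model from a config mapping, e.g.
    ``{"exponential": {"rate": 0.05}}``."""
    if len(spec) != 1:
        raise ValueError("hazard spec must have exactly one key")
    (name, params), = spec.items()
    if name == "exponential":
        return Exponential(**params)
    if name == "weibull":
        return Weibull(**params)
    if name == "piecewise_exponential":
        return PiecewiseExponential(
            tuple(params["breaks"]), tuple(params["rates"])
        )
    raise ValueError(f"unknown hazard model {name!r}")


@dataclass
class SimScenario:
    """A two-arm trial design with known ground truth."""

    n_per_arm: tuple[int, int]
    hazards: tuple[HazardModel, HazardModel]
    followup: float
    admin_censor_time: float | None = None
    random_censor_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.n_per_arm, int):
            self.n_per_arm = (self.n_per_arm, self.n_per_arm)
        if self.followup <= 0:
            raise ValueError("followup must be positive")
        if self.random_censor_rate < 0:
            raise ValueError("random_censor_rate must be >= 0")


@dataclass
class DigitizerNoise:
    """Corruption model for the virtual digitizer.

    ``click_keep_prob`` thins the step-corner points the way a manual
    clicker subsamples a trace; ``surv_jitter_sd``/``time_jitter_sd``
    add Gaussian coordinate error; ``tilt_verticals`` replaces each
    vertical drop's two equal times by times differing by less than
    0.001, the innate artifact of trace-based extraction.
    """

    click_keep_prob: float = 0.6
    surv_jitter_sd: float = 0.005
    time_jitter_sd: float = 0.1
    tilt_verticals: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.click_keep_prob <= 1.0:
            raise ValueError("click_keep_prob must be in (0, 1]")
        if self.surv_jitter_sd < 0 or self.time_jitter_sd < 0:
            raise ValueError("jitter SDs must be >= 0")


PERFECT_DIGITIZER = DigitizerNoise(
    click_keep_prob=1.0, surv_jitter_sd=0.0, time_jitter_sd=0.0, tilt_verticals=False
)


def default_scenario(seed: int = 0, hr: float = 0.7, n_per_arm: int = 200) -> SimScenario:
    """Benchmark trial: exponential control with median 12 time units,
    proportional treatment effect, 36 units of follow-up, administrative
    censoring at follow-up end and mild random loss to follow-up."""
    base = math.log(2) / 12.0
    return SimScenario(
        n_per_arm=(n_per_arm, n_per_arm),
        hazards=(Exponential(base), Exponential(hr * base)),
        followup=36.0,
        admin_censor_time=36.0,
        random_censor_rate=0.02,
        seed=seed,
    )


def simulate_trial(scenario: SimScenario) -> IPDataset:
    """Draw one trial: per-arm event times from the hazard model,
    censoring as the minimum of random loss to follow-up, administrative
    cut-off and end of follow-up. Deterministic given the seed."""
    rng = np.random.default_rng(scenario.seed)
    admin = min(
        scenario.admin_censor_time
        if scenario.admin_censor_time is not None
        else np.inf,
        scenario.followup,
    )
    parts = []
    for a, (n, hz) in enumerate(zip(scenario.n_per_arm, scenario.hazards)):
        t_event = hz.sample(n, rng)
        if scenario.random_censor_rate > 0:
            t_cens = rng.exponential(1.0 / scenario.random_censor_rate, size=n)
        else:
            t_cens = np.full(n, np.inf)
        t_cens = np.minimum(t_cens, admin)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        parts.append(IPDataset(time, event, np.full(n, a, int)))
    return IPDataset.concat(parts, provenance="simulated")


def render_digitized(
    true_ipd: IPDataset,
    noise: DigitizerNoise,
    atrisk_times: np.ndarray | list[float],
) -> tuple[DigitizedCurve, AtRiskTable, ArmTotals]:
    """Virtual digitizer: exact KM step corners of one arm, corrupted.

    Emits both corner points of each step (pre-drop and post-drop) so a
    faithful trace is representable; thinning never removes the first
    or last point. Censoring marks are not rendered — the reconstruction
    ignores them by design. The at-risk table and totals are exact.
    """
    if np.unique(true_ipd.arm).size > 1:
        raise ValueError("render one arm at a time")
    rng = np.random.default_rng(noise.seed)
    km = km_estimate(true_ipd)
    t_end = float(true_ipd.time.max())

    pts_t = [0.0]
    pts_s = [1.0]
    prev_s = 1.0
    for tj, sj in zip(km.times, km.surv):
        pts_t.extend([float(tj), float(tj)])
        pts_s.extend([prev_s, float(sj)])
        prev_s = float(sj)
    if not km.times.size or t_end > km.times[-1]:
        pts_t.append(t_end)
        pts_s.append(prev_s)
    t = np.array(pts_t)
    s = np.array(pts_s)

    if noise.tilt_verticals and t.size > 1:
        # post-drop corner lands fractionally later than the pre-drop
        # one; the offset never reaches the next corner so click order
        # (and time monotonicity) is preserved
        dup = np.flatnonzero(np.diff(t) == 0.0) + 1
        offs = rng.uniform(0.0002, 0.0009, size=dup.size)
        gap_next = np.where(dup < t.size - 1, t[np.minimum(dup + 1, t.size - 1)] - t[dup], np.inf)
        t[dup] += np.minimum(offs, 0.4 * gap_next)

    if noise.click_keep_prob < 1.0:
        keep = rng.random(t.size) < noise.click_keep_prob
        keep[0] = keep[-1] = True
        t, s = t[keep], s[keep]

    if noise.time_jitter_sd > 0:
        t = t + rng.normal(0.0, noise.time_jitter_sd, size=t.size)
    if noise.surv_jitter_sd > 0:
        s = s + rng.normal(0.0, noise.surv_jitter_sd, size=s.size)

    raw = DigitizedCurve(t, s, preprocessed=False)

    ar_t = np.asarray(atrisk_times, dtype=float)
    counts = np.array([(true_ipd.time >= tt).sum() for tt in ar_t], dtype=int)
    ok = counts >= 1
    table = AtRiskTable(ar_t[ok], counts[ok])
    totals = ArmTotals(n_total=len(true_ipd), d_total=true_ipd.n_events)
    return raw, table, totals


@dataclass
class ScenarioSummary:
    """Replicate-level metrics and their summary for one scenario."""

    per_rep: pd.DataFrame
    n_failed: int
    summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.summary:
            d = self.per_rep["abs_hr_pct_diff"]
            o = self.per_rep["ci_nonoverlap_pct"]
            self.summary = {
                "n_reps": int(len(self.per_rep)) + self.n_failed,
                "n_failed": self.n_failed,
                "hr_diff_mean": float(d.mean()),
                "hr_diff_sd": float(d.std(ddof=1)) if len(d) > 1 else 0.0,
                "hr_diff_median": float(d.median()),
                "hr_diff_min": float(d.min()),
                "hr_diff_max": float(d.max()),
                "nonoverlap_mean": float(o.mean()),
                "nonoverlap_sd": float(o.std(ddof=1)) if len(o) > 1 else 0.0,
                "nonoverlap_median": float(o.median()),
                "n_lt_5": int((d < 5).sum()),
                "n_5_to_10": int(((d >= 5) & (d < 10)).sum()),
                "n_ge_10": int((d >= 10).sum()),
            }


def evaluate_scenario(
    scenario: SimScenario,
    noise: DigitizerNoise,
    atrisk_spacing: float | None = None,
    n_reps: int = 1,
    seed: int = 0,
    apply_preprocess: bool = True,
    use_atrisk: bool = True,
    use_totals: bool = True,
) -> ScenarioSummary:
    """Run the full loop n_reps times and summarize the agreement
    between HRs fitted on reconstructed vs. source patient data.

    ``apply_preprocess=False`` and ``use_atrisk=False`` are the
    sensitivity ablations: skip coordinate adjustment, or withhold the
    at-risk table (keeping only the baseline patient count).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    spacing = atrisk_spacing if atrisk_spacing is not None else scenario.followup / 8.0
    atrisk_times = np.arange(0.0, scenario.followup + spacing / 2, spacing)
    ss = np.random.SeedSequence(seed)
    rows = []
    n_failed = 0
    import warnings as _warnings

    for rep, child in enumerate(ss.spawn(n_reps)):
        s_trial, s_arm0, s_arm1 = (
            int(x) for x in child.generate_state(3) % (2**31)
        )
        scen = replace(scenario, seed=s_trial)
        true_ipd = simulate_trial(scen)
        try:
            hr_true = cox_hr(true_ipd)
            arms = []
            for a, s_noise in ((0, s_arm0), (1, s_arm1)):
                arm_ipd = true_ipd.select_arm(a)
                raw, table, totals = render_digitized(
                    arm_ipd, replace(noise, seed=s_noise), atrisk_times
                )
                curve = preprocess_curve(raw)[0] if apply_preprocess else raw
                if not use_atrisk:
                    table = AtRiskTable(table.times[:1], table.counts[:1])
                    totals = ArmTotals(n_total=totals.n_total)
                elif not use_totals:
                    totals = ArmTotals()
                with _warnings.catch_warnings():
                    _warnings.simplefilter("ignore")
                    res = reconstruct_arm(curve, table, totals)
                arms.append(
                    IPDataset(
                        res.ipd.time, res.ipd.event, np.full(len(res.ipd), a, int)
                    )
                )
            hr_rec = cox_hr(IPDataset.concat(arms, provenance="reconstructed"))
            rows.append(
                {
                    "rep": rep,
                    "hr_true": hr_true.hr,
                    "hr_rec": hr_rec.hr,
                    "abs_hr_pct_diff": abs_hr_pct_diff(hr_rec.hr, hr_true.hr),
                    "ci_nonoverlap_pct": ci_nonoverlap_pct(hr_true.ci, hr_rec.ci),
                }
            )
        except Exception:
            n_failed += 1
    per_rep = pd.DataFrame(
        rows,
        columns=["rep", "hr_true", "hr_rec", "abs_hr_pct_diff", "ci_nonoverlap_pct"],
    )
    return ScenarioSummary(per_rep=per_rep, n_failed=n_failed)
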