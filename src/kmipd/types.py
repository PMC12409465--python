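"""Core containers shared across the reconstruction pipeline.

Time is treated as unitless throughout: months, weeks or years are all
fine as long as curve coordinates, at-risk times and follow-up are given
on the same scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DigitizedCurve",
    "AtRiskTable",
    "ArmTotals",
    "IPDataset",
    "KMEstimate",
    "HREstimate",
]


@dataclass
class DigitizedCurve:
    """Ordered (time, survival) click coordinates for one treatment arm.

    Raw digitizer output (``preprocessed=False``) may contain negative
    times, probabilities slightly above 1 and local increases; a
    preprocessed curve is anchored at (0, 1), time-sorted and monotone
    non-increasing.
    """

    times: np.ndarray
    surv: np.ndarray
    arm_label: str = ""
    preprocessed: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.surv = np.asarray(self.surv, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.surv.shape:
            raise ValueError("times and surv must be 1-D arrays of equal length")
        if self.times.size == 0:
            raise ValueError("a digitized curve needs at least one point")
        if self.preprocessed:
            self.validate_preprocessed()

    def validate_preprocessed(self) -> None:
        if self.times[0] != 0.0 or self.surv[0] != 1.0:
            raise ValueError("preprocessed curve must start at (0, 1)")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("preprocessed times must be non-decreasing")
        if np.any(np.diff(self.surv) > 0):
            raise ValueError("preprocessed survival must be non-increasing")
        if self.surv.min() < 0.0 or self.surv.max() > 1.0:
            raise ValueError("preprocessed survival must lie in [0, 1]")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.times.tolist(), self.surv.tolist()))


@dataclass
class AtRiskTable:
    """Published numbers at risk: counts of patients still under
    follow-up at the reported time points beneath a KM plot."""

    times: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.times.shape != self.counts.shape or self.times.ndim != 1:
            raise ValueError("times and counts must be 1-D arrays of equal length")
        if self.times.size == 0:
            raise ValueError("at-risk table must have at least one entry")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("at-risk times must be strictly increasing")
        if np.any(np.diff(self.counts) > 0):
            bad = int(np.flatnonzero(np.diff(self.counts) > 0)[0])
            raise ValueError(
                "at-risk counts must be non-increasing; "
                f"count rises from {self.counts[bad]} at t={self.times[bad]} "
                f"to {self.counts[bad + 1]} at t={self.times[bad + 1]}"
            )
        if np.any(self.counts < 1):
            raise ValueError("at-risk counts must be >= 1 at all reported times")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class ArmTotals:
    """Optional published totals for one arm: total patients randomized
    and total events observed."""

    n_total: int | None = None
    d_total: int | None = None

    def __post_init__(self) -> None:
        if self.n_total is not None and self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if self.d_total is not None and self.d_total < 0:
            raise ValueError("d_total must be non-negative")
        if (
            self.n_total is not None
            and self.d_total is not None
            and self.d_total > self.n_total
        ):
            raise ValueError("d_total cannot exceed n_total")


@dataclass
class IPDataset:
    """Per-patient records: follow-up time, event indicator (1 = event,
    0 = censored) and an integer arm indicator."""

    time: np.ndarray
    event: np.ndarray
    arm: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        self.arm = np.asarray(self.arm, dtype=int)
        n = self.time.size
        if self.event.size != n or self.arm.size != n:
            raise ValueError("time, event and arm must have equal length")
        if n and (not np.all(np.isfinite(self.time)) or self.time.min() < 0):
            raise ValueError("times must be finite and non-negative")
        if n and not np.isin(self.event, (0, 1)).all():
            raise ValueError("event must be 0 or 1")

    def __len__(self) -> int:
        return int(self.time.size)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "event": self.event, "arm": self.arm})

    def select_arm(self, arm: int) -> "IPDataset":
        mask = self.arm == arm
        return IPDataset(
            self.time[mask], self.event[mask], self.arm[mask], self.provenance
        )

    @staticmethod
    def concat(datasets: list["IPDataset"], provenance: str = "") -> "IPDataset":
        return IPDataset(
            np.concatenate([d.time for d in datasets]),
            np.concatenate([d.event for d in datasets]),
            np.concatenate([d.arm for d in datasets]),
            provenance,
        )


@dataclass
class KMEstimate:
    """Product-limit estimate with per-event-time bookkeeping.

    ``times`` holds the distinct event times; ``surv`` the KM estimate
    just after each; ``var_log`` the cumulative Greenwood sums
    sum d_j / (n_j (n_j - d_j)) used for pointwise confidence bands.
    """

    times: np.ndarray
    surv: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    n_censor: np.ndarray
    var_log: np.ndarray | None = None
    n_total: int = 0

    def evaluate(self, t: np.ndarray | float) -> np.ndarray:
        """Right-continuous step evaluation; S(t) = 1 before the first event."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.times.size == 0:  # all-censored: S(t) = 1 everywhere
            return np.ones_like(t)
        idx = np.searchsorted(self.times, t, side="right") - 1
        return np.where(idx >= 0, self.surv[np.maximum(idx, 0)], 1.0)

    def confidence_bands(self, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
        """Pointwise log(-log) Greenwood bands at the event times."""
        from scipy.stats import norm

        if self.var_log is None:
            raise ValueError("Greenwood terms unavailable")
        z = norm.ppf(1 - alpha / 2)
        lo = np.ones_like(self.surv)
        up = np.ones_like(self.surv)
        with np.errstate(divide="ignore", invalid="ignore"):
            logs = np.log(self.surv)
            se_cll = np.sqrt(self.var_log) / np.abs(logs)
            interior = (self.surv > 0) & (self.surv < 1)
            lo[interior] = self.surv[interior] ** np.exp(z * se_cll[interior])
            up[interior] = self.surv[interior] ** np.exp(-z * se_cll[interior])
        zero = self.surv == 0
        lo[zero] = 0.0
        up[zero] = 0.0
        return lo, up


@dataclass
class HREstimate:
    """Hazard ratio with 95% CI from a two-arm proportional-hazards fit."""

    hr: float
    lo: float
    up: float
    log_hr: float
    se_log_hr: float
    warnings: list[str] = field(default_factory=list)

    @property
    def ci(self) -> tuple[float, float]:
        return (self.lo, self.up)
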