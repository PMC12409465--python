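"""Agreement and accuracy metrics for reconstructed survival data.

Two families of quantities:

* agreement of a reconstructed hazard ratio (HR_r, CI_r) with the
  originally published one (HR_o, CI_o) — the absolute percentage HR
  difference and the percentage of the original CI left uncovered by
  the reconstructed CI; both are deliberately asymmetric, normalized by
  the original (published) quantity;
* fidelity of the fitted KM step function to the read-in (preprocessed)
  click coordinates — RMSE, mean and maximum absolute error over the
  click grid, plus a two-sample Kolmogorov-Smirnov comparison of the
  two survival-probability vectors at that grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import ks_2samp

from .types import DigitizedCurve, KMEstimate

__all__ = [
    "abs_hr_pct_diff",
    "ci_nonoverlap_pct",
    "AccuracyReport",
    "accuracy_report",
]


def abs_hr_pct_diff(hr_r: float, hr_o: float) -> float:
    """Absolute percentage difference |HR_r - HR_o| / HR_o x 100."""
    if hr_o <= 0:
        raise ValueError("original HR must be positive")
    return abs(hr_r - hr_o) / hr_o * 100.0


def ci_nonoverlap_pct(
    ci_o: tuple[float, float], ci_r: tuple[float, float]
) -> float:
    """Percentage of the original CI not covered by the reconstructed CI.

    overlap = max(0, min(U_o, U_r) - max(L_o, L_r));
    returns (1 - overlap / (U_o - L_o)) x 100, clipped into [0, 100].
    0 whenever CI_r contains CI_o; 100 for disjoint intervals.
    """
    lo_o, up_o = ci_o
    lo_r, up_r = ci_r
    if up_o <= lo_o:
        raise ValueError("original CI is degenerate (upper <= lower)")
    if up_r < lo_r:
        raise ValueError("reconstructed CI has upper < lower")
    overlap = max(0.0, min(up_o, up_r) - max(lo_o, lo_r))
    return float(np.clip((1.0 - overlap / (up_o - lo_o)) * 100.0, 0.0, 100.0))


@dataclass
class AccuracyReport:
    rmse: float
    mae: float
    max_ae: float
    ks_stat: float
    ks_p: float


def accuracy_report(readin: DigitizedCurve, km: KMEstimate) -> AccuracyReport:
    """Compare the fitted KM step function with the read-in coordinates.

    "Read-in" means the extracted-and-adjusted click coordinates, not
    the original trial's patient data: this measures how faithfully the
    reconstruction reproduces the curve it was given.
    """
    est = km.evaluate(readin.times)
    diff = est - readin.surv
    ks = ks_2samp(est, readin.surv, method="asymp")
    return AccuracyReport(
        rmse=float(np.sqrt(np.mean(diff**2))),
        mae=float(np.mean(np.abs(diff))),
        max_ae=float(np.max(np.abs(diff))),
        ks_stat=float(ks.statistic),
        ks_p=float(ks.pvalue),
    )
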