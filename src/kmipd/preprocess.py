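"""Turn raw digitizer clicks into a valid survival step sequence.

Click- and trace-based digitizers produce coordinates that violate the
defining properties of a Kaplan-Meier curve: the first click may land at
a slightly negative time, probabilities may exceed 1 by a pixel's worth
of jitter, and local noise creates spurious increases. Reconstruction
needs a curve that starts at (0, 1) and is monotone non-increasing;
this module enforces exactly that, and nothing more (no smoothing, no
resampling).

The adjustment pipeline, applied in order:

1. stable sort by time (click order within ties is preserved);
2. hard clamp of survival into [0, 1];
3. anchoring at (0, 1): clicks at time <= 0 are absorbed into the
   anchor; if the earliest click time is positive, an explicit (0, 1)
   point is prepended instead so the genuinely observed click survives;
4. forward monotone adjustment: any survival value above its
   predecessor is replaced by the predecessor's value;
5. removal of exact consecutive duplicate points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import DigitizedCurve

__all__ = ["PreprocessReport", "preprocess_curve"]


@dataclass
class PreprocessReport:
    """Bookkeeping of what preprocessing changed."""

    n_raw: int
    n_adjusted_monotone: int = 0
    n_deduplicated: int = 0
    anchor_shifted: bool = False
    n_clamped: int = 0
    n_absorbed_into_anchor: int = 0
    n_time_ties: int = 0

    def any_change(self) -> bool:
        return bool(
            self.n_adjusted_monotone
            or self.n_deduplicated
            or self.anchor_shifted
            or self.n_clamped
            or self.n_absorbed_into_anchor
        )


def preprocess_curve(raw: DigitizedCurve) -> tuple[DigitizedCurve, PreprocessReport]:
    """Adjust raw click coordinates into a valid preprocessed curve.

    Returns the adjusted curve (``preprocessed=True``) and a report
    counting each action. Degenerate inputs (a single click, a flat
    curve) are allowed; an empty curve is rejected by the
    :class:`~kmipd.types.DigitizedCurve` constructor itself.
    """
    report = PreprocessReport(n_raw=len(raw))

    order = np.argsort(raw.times, kind="stable")
    t = raw.times[order].copy()
    s = raw.surv[order].copy()

    clamped = (s < 0.0) | (s > 1.0)
    report.n_clamped = int(clamped.sum())
    s = np.clip(s, 0.0, 1.0)

    # Anchor at (0, 1). Clicks at negative times carry no information
    # beyond "the curve starts here" and are absorbed into the anchor.
    neg = t < 0.0
    report.n_absorbed_into_anchor = int(neg.sum())
    t, s = t[~neg], s[~neg]
    if t.size == 0:
        t, s = np.array([0.0]), np.array([1.0])
        report.anchor_shifted = True
    elif t[0] == 0.0:
        if s[0] != 1.0 or report.n_absorbed_into_anchor:
            report.anchor_shifted = s[0] != 1.0
            s[0] = 1.0
    else:
        t = np.concatenate(([0.0], t))
        s = np.concatenate(([1.0], s))
        report.anchor_shifted = True

    report.n_time_ties = int((np.diff(t) == 0).sum())

    # Forward monotone pass: a survival value above its predecessor is
    # digitizer noise; pull it down to the predecessor.
    adjusted = 0
    for i in range(1, s.size):
        if s[i] > s[i - 1]:
            s[i] = s[i - 1]
            adjusted += 1
    report.n_adjusted_monotone = adjusted

    # Drop exact consecutive duplicates only; near-duplicates carry
    # genuine trace information and the reconstruction tolerates them.
    if t.size > 1:
        keep = np.concatenate(([True], (np.diff(t) != 0) | (np.diff(s) != 0)))
        report.n_deduplicated = int((~keep).sum())
        t, s = t[keep], s[keep]

    curve = DigitizedCurve(t, s, arm_label=raw.arm_label, preprocessed=True)
    return curve, report
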