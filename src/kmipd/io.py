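"""Readers and writers for the on-disk dialects.

Canonical coordinate files are comma-separated two-column text
(``time,surv``) with an optional single header row; tab- and
space-delimited files from other digitizers are accepted via the
``dialect`` argument. Unicode minus signs (U+2212), as produced by some
figure-extraction tools, are accepted wherever a number is expected.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import ArmTotals, AtRiskTable, DigitizedCurve, IPDataset

__all__ = [
    "read_coordinates",
    "write_coordinates",
    "read_ipd",
    "write_ipd",
    "ArmConfig",
    "RunConfig",
    "read_run_config",
]

_DELIMS = {"comma": ",", "tab": "\t", "space": None, "auto": None}

# ASCII hyphen-minus plus the Unicode minus/hyphen variants seen in
# published-figure extractions.
_MINUS = str.maketrans({"−": "-", "–": "-", "—": "-"})


def _to_float(token: str, row: int, path: str) -> float:
    try:
        return float(token.translate(_MINUS))
    except ValueError:
        raise ValueError(
            f"{path}: non-numeric value {token!r} in data row {row}"
        ) from None


def _split_row(line: str, delim: str | None) -> list[str]:
    line = line.strip().strip("()")
    if delim is None:
        return [t for t in re.split(r"[,\t ]+", line) if t]
    return [t.strip() for t in line.split(delim) if t.strip()]


def read_coordinates(
    path: str | os.PathLike, dialect: str = "auto", arm_label: str = ""
) -> DigitizedCurve:
    """Read a two-column (time, survival) coordinate file.

    Returns a raw curve (``preprocessed=False``) preserving row order
    exactly: no sorting, deduplication or clamping happens here — that
    is the preprocessing step's job.
    """
    if dialect not in _DELIMS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(_DELIMS)}")
    delim = _DELIMS[dialect]
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: no data rows")

    def _numeric_row(line: str) -> bool:
        toks = _split_row(line, delim)
        if len(toks) < 2:
            return False
        try:
            for t in toks[:2]:
                float(t.translate(_MINUS))
            return True
        except ValueError:
            return False

    start = 0
    if not _numeric_row(lines[0]):  # single header row, auto-detected
        start = 1
    if start >= len(lines):
        raise ValueError(f"{path}: no data rows")
    times, surv = [], []
    for i, line in enumerate(lines[start:], start=start + 1):
        toks = _split_row(line, delim)
        if len(toks) < 2:
            raise ValueError(f"{path}: expected 2 columns in data row {i}")
        times.append(_to_float(toks[0], i, str(path)))
        surv.append(_to_float(toks[1], i, str(path)))
    return DigitizedCurve(np.array(times), np.array(surv), arm_label=arm_label)


def write_coordinates(curve: DigitizedCurve, path: str | os.PathLike) -> None:
    """Write a curve in the canonical dialect (6-decimal precision)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("time,surv\n")
        for t, s in zip(curve.times, curve.surv):
            fh.write(f"{t:.6f},{s:.6f}\n")


def write_ipd(ipd: IPDataset, path: str | os.PathLike) -> None:
    """Write per-patient records as CSV with header ``time,event,arm``."""
    ipd.to_frame().to_csv(path, index=False)


def read_ipd(path: str | os.PathLike) -> IPDataset:
    df = pd.read_csv(path)
    missing = {"time", "event", "arm"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return IPDataset(
        df["time"].to_numpy(float),
        df["event"].to_numpy(int),
        df["arm"].to_numpy(int),
        provenance=str(path),
    )


@dataclass
class ArmConfig:
    """One arm of a run: its coordinate file, at-risk table and totals."""

    coords: Path
    at_risk: AtRiskTable | None
    totals: ArmTotals
    label: str = ""


@dataclass
class RunConfig:
    arms: list[ArmConfig]
    time_unit: str = ""
    seed: int | None = None
    options: dict = field(default_factory=dict)


def read_run_config(path: str | os.PathLike) -> RunConfig:
    """Load and validate a YAML run description.

    Schema: ``arms`` is a list of mappings with keys ``coords`` (path),
    optional ``at_risk: {times: [...], counts: [...]}``, optional
    ``n_total``/``d_total`` and ``label``; global keys ``time_unit``
    and ``seed`` are optional. At-risk invariants (strictly increasing
    times, non-increasing positive counts) are checked at load.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "arms" not in raw:
        raise ValueError(f"{path}: config must be a mapping with an 'arms' list")
    base = Path(path).parent
    arms: list[ArmConfig] = []
    for i, spec in enumerate(raw["arms"]):
        coords = Path(spec["coords"])
        if not coords.is_absolute():
            coords = base / coords
        if not coords.exists():
            raise FileNotFoundError(f"arm {i}: coordinate file {coords} not found")
        at_risk = None
        if "at_risk" in spec and spec["at_risk"] is not None:
            ar = spec["at_risk"]
            at_risk = AtRiskTable(np.asarray(ar["times"]), np.asarray(ar["counts"]))
        totals = ArmTotals(spec.get("n_total"), spec.get("d_total"))
        arms.append(ArmConfig(coords, at_risk, totals, spec.get("label", f"arm{i}")))
    if not arms:
        raise ValueError(f"{path}: at least one arm required")
    return RunConfig(
        arms=arms,
        time_unit=raw.get("time_unit", ""),
        seed=raw.get("seed"),
        options=raw.get("options", {}),
    )
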