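"""Cutoff derivation from a labeled training cohort.

The published cutoffs were set by locating the gap between the target
secretion's methylation range and the ranges of all other secretions.  The
rule implemented here reproduces that construction with a configurable
safety margin:

* direction ``below`` (hypomethylated target): cutoff = floor(min of
  non-target values) − 1 − margin; the call fires when value < cutoff.
* direction ``above`` (hypermethylated target): cutoff = ceil(max of
  non-target values) + margin; the call fires when value > cutoff.

All published cutoffs are integers; derived cutoffs are therefore integers
too.  The published panel was set with heterogeneous margins (0 for B7,
effectively 0 for NB21, 4 points for MB4), so the shipped defaults in
:mod:`methylfluid.panel` remain authoritative; derivation serves validation
and new markers.  Conditional (pre-test-restricted) cutoffs are derived by
removing the excluded fluids' values from the non-target pool and re-running
the same rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .panel import BodyFluid

__all__ = ["CutoffResult", "summarize_cohort", "derive_cutoff", "calibration_report"]


@dataclass(frozen=True)
class CutoffResult:
    cutoff: int
    direction: str  # below | above
    overlap_fraction: float  # fraction of target values the rule misses
    ranges_overlap: bool

    def fires(self, value: float) -> bool:
        return value < self.cutoff if self.direction == "below" else value > self.cutoff


def summarize_cohort(samples: Sequence[tuple[object, Mapping[str, float]]]) -> pd.DataFrame:
    """Per-(fluid, marker) n/mean/sd/min/max over labeled collapsed profiles.

    ``samples`` is a sequence of (single-source fluid label, marker->value).
    Mixture labels are rejected: range statistics of blended stains would
    corrupt the calibration pools.
    """
    rows = []
    for label, profile in samples:
        if hasattr(label, "is_single_source"):
            if not label.is_single_source:
                raise ValueError("mixture-labeled sample passed to summarize_cohort")
            label = label.components[0][0]
        name = label.value if isinstance(label, BodyFluid) else str(label)
        if "+" in name:
            raise ValueError("mixture-labeled sample passed to summarize_cohort")
        for marker, value in profile.items():
            rows.append({"fluid": name, "marker": marker, "value": value})
    if not rows:
        raise ValueError("no labeled profiles supplied")
    long = pd.DataFrame(rows)
    out = (
        long.groupby(["fluid", "marker"])["value"]
        .agg(n="size", mean="mean", sd="std", min="min", max="max")
        .reset_index()
    )
    out["sd"] = out["sd"].fillna(0.0)  # single-sample cells
    return out


def derive_cutoff(
    target_values: Sequence[float],
    nontarget_values: Sequence[float],
    direction: str,
    margin: int = 0,
) -> CutoffResult:
    """Place a cutoff in the gap between target and non-target ranges.

    Every non-target value is guaranteed to fail the derived rule.  When the
    target and non-target ranges overlap, the result carries
    ``ranges_overlap=True`` and ``overlap_fraction`` — the fraction of
    target values the rule fails to call (the weak-marker situation of the
    nasal assays).
    """
    if direction not in ("below", "above"):
        raise ValueError(f"direction must be 'below' or 'above', got {direction!r}")
    if len(nontarget_values) == 0:
        raise ValueError("non-target values must be non-empty")
    if margin < 0:
        raise ValueError("margin must be >= 0")

    if direction == "below":
        cutoff = int(math.floor(min(nontarget_values))) - 1 - margin
    else:
        cutoff = int(math.ceil(max(nontarget_values))) + margin
    cutoff = max(0, min(100, cutoff))

    result = CutoffResult(cutoff, direction, 0.0, False)
    if len(target_values):
        missed = sum(1 for v in target_values if not result.fires(v))
        if direction == "below":
            overlap = max(target_values) >= min(nontarget_values)
        else:
            overlap = min(target_values) <= max(nontarget_values)
        result = CutoffResult(cutoff, direction, missed / len(target_values), overlap)
    return result


def calibration_report(summary: pd.DataFrame) -> str:
    """Human-readable per-marker range table from a cohort summary."""
    lines = []
    for marker, block in summary.groupby("marker"):
        lines.append(f"== {marker} ==")
        for _, row in block.sort_values("fluid").iterrows():
            lines.append(
                f"  {row['fluid']:<22s} n={int(row['n']):>5d}  "
                f"mean={row['mean']:6.2f}  sd={row['sd']:6.2f}  "
                f"range {row['min']:6.2f} – {row['max']:6.2f}"
            )
    return "\n".join(lines)
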