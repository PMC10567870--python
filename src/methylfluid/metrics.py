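"""Confusion summaries for marker validation.

Scores rule firings against known composition labels in the layout of a
per-marker validation table: one block per marker, one column per truth
cohort.  Target cohorts contribute true-positive / false-negative counts,
non-target cohorts false-positive / true-negative counts; sensitivity and
specificity are percentages rounded half-up to two decimals and recompute
exactly from the counts.  Sensitivity over an empty target cohort is
reported as not applicable (NaN), never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd

from .panel import (
    MARKER_ORDER,
    NASAL_PAIR_LABEL,
    BodyFluid,
    PreTestPanel,
    ThresholdRule,
    default_rules,
    resolve_thresholds,
)
from .qc import check_sample, collapse_replicates
from .records import SampleRecord

__all__ = ["ConfusionRow", "score_marker", "percent", "validation_report",
           "marker_fires_for"]


def percent(count: int, total: int) -> float:
    """100·count/total, two decimals, half-up (so 14/23 → 60.87)."""
    if total == 0:
        return float("nan")
    q = Decimal(100) * Decimal(count) / Decimal(total)
    return float(q.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionRow:
    n_target: int
    n_nontarget: int
    true_positive: int
    false_positive: int
    true_negative: int
    false_negative: int

    @property
    def sensitivity(self) -> float:
        return percent(self.true_positive, self.n_target)

    @property
    def specificity(self) -> float:
        return percent(self.true_negative, self.n_nontarget)


def score_marker(
    results: Iterable[tuple[str, bool]],
    target: str | set[str],
) -> ConfusionRow:
    """Tally one marker's firings against truth labels.

    ``results`` yields (truth label, rule fired); ``target`` names the
    label(s) the marker is meant to flag.
    """
    targets = {target} if isinstance(target, str) else set(target)
    tp = fp = tn = fn = 0
    for label, fired in results:
        if label in targets:
            tp += fired
            fn += not fired
        else:
            fp += fired
            tn += not fired
    if tp + fn + fp + tn == 0:
        raise ValueError("empty input")
    return ConfusionRow(tp + fn, fp + tn, tp, fp, tn, fn)


# truth fluids a marker's firing should count as a true positive for
_TARGET_LABELS: dict[str, set[str]] = {
    "NB21": {BodyFluid.NASAL_SECRETION.value, BodyFluid.NASAL_BLOOD.value},
    "B7": {BodyFluid.PERIPHERAL_BLOOD.value},
    "MB4": {BodyFluid.MENSTRUAL_BLOOD.value},
    "SA4": {BodyFluid.SALIVA.value},
    "V2": {BodyFluid.VAGINAL_SECRETION.value},
    "N27SE": {BodyFluid.NASAL_SECRETION.value, BodyFluid.NASAL_BLOOD.value,
              BodyFluid.SPERM_SECRETION.value},
}

# outcomes that count as identifying each marker's target
_TARGET_OUTCOMES: dict[str, set[str]] = {
    "NB21": {"nasal_pair_full"},
    "B7": {"peripheral_blood_pure"},
    "MB4": {"menstrual_blood_full", "menstrual_sperm_mixture"},
    "SA4": {"saliva_full", "saliva_partial"},
    "V2": {"vaginal_full"},
    "N27SE": {"sperm_full", "nasal_band"},
}


def marker_fires_for(
    marker: str,
    value: float,
    pretests: PreTestPanel,
    rules: Sequence[ThresholdRule] | None = None,
) -> bool:
    """Whether a marker's target-identifying tier fires on one value."""
    tiers = resolve_thresholds(marker, pretests, rules)
    fired = next((t for t in tiers if t.fires(value)), None)
    return fired is not None and fired.outcome in _TARGET_OUTCOMES[marker]


def validation_report(
    cohort: Sequence[SampleRecord],
    rules: Sequence[ThresholdRule] | None = None,
    allow_single: bool = False,
) -> pd.DataFrame:
    """Validation-table-style confusion summary of a labeled cohort.

    Each sample must carry a single-source ``true_composition``.  Returns
    one row per (marker, truth fluid cohort) with n and TP/FP/TN/FN counts
    plus sensitivity/specificity percentages; per marker block the counts
    sum to the number of classified samples.  Truth cohorts with no
    measurement for a marker are omitted with a warning column note.
    """
    rules = default_rules() if rules is None else rules
    per_marker: dict[str, list[tuple[str, bool]]] = {m: [] for m in MARKER_ORDER}

    for rec in cohort:
        label = rec.true_composition.split(":")[0]
        if "+" in rec.true_composition:
            raise ValueError(f"{rec.sample_id}: mixture label in validation cohort")
        report = check_sample(rec)
        profile = collapse_replicates(rec, report, allow_single=allow_single)
        for marker, value in profile.items():
            per_marker[marker].append(
                (label, marker_fires_for(marker, value, rec.pretests, rules))
            )

    rows = []
    for marker in MARKER_ORDER:
        scored = per_marker[marker]
        if not scored:
            continue
        targets = _TARGET_LABELS[marker]
        cohorts = sorted({label for label, _ in scored})
        for truth in cohorts:
            subset = [(lab, fired) for lab, fired in scored if lab == truth]
            n = len(subset)
            fired_n = sum(f for _, f in subset)
            if truth in targets:
                rows.append(
                    {
                        "marker": marker,
                        "cohort": truth,
                        "is_target": True,
                        "n": n,
                        "true_positive": fired_n,
                        "false_positive": 0,
                        "true_negative": 0,
                        "false_negative": n - fired_n,
                        "sensitivity": percent(fired_n, n),
                        "specificity": float("nan"),
                    }
                )
            else:
                rows.append(
                    {
                        "marker": marker,
                        "cohort": truth,
                        "is_target": False,
                        "n": n,
                        "true_positive": 0,
                        "false_positive": fired_n,
                        "true_negative": n - fired_n,
                        "false_negative": 0,
                        "sensitivity": float("nan"),
                        "specificity": percent(n - fired_n, n),
                    }
                )
    return pd.DataFrame(rows)
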