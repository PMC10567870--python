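"""Sample acceptance rules and duplicate reduction.

All assays are run in duplicate.  A sample is analyzable when its bisulfite
conversion control passed and its DNA concentration reaches the minimum
input for conversion (2.5 ng/µl); a marker is analyzable when its duplicate
measurements agree within the deviation bound (5 percentage points —
absolute points, not relative percent, so values near 0% are not penalised).
Failing markers are dropped, never imputed; downstream classification
tolerates partial profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .records import SampleRecord

__all__ = ["QCReport", "check_sample", "collapse_replicates", "qc_frame"]

DEFAULT_DEVIATION_BOUND = 5.0  # percentage points between duplicates
DEFAULT_MIN_CONCENTRATION = 2.5  # ng/µl


@dataclass
class QCReport:
    sample_id: str
    conversion_control_pass: bool
    concentration_ok: bool
    deviation: dict[str, float | None]  # marker -> |rep1 - rep2|; None if single
    status: dict[str, str]  # marker -> pass | fail_deviation | missing
    deviation_bound: float = DEFAULT_DEVIATION_BOUND

    @property
    def sample_usable(self) -> bool:
        return self.conversion_control_pass and self.concentration_ok


def check_sample(
    sample: SampleRecord,
    deviation_bound: float = DEFAULT_DEVIATION_BOUND,
    min_concentration: float = DEFAULT_MIN_CONCENTRATION,
    markers: Sequence[str] | None = None,
) -> QCReport:
    """Apply the acceptance rules to one sample.

    ``markers`` (default: the markers present in the record) lets callers
    flag panel markers that were not assayed as ``missing``.
    """
    if not sample.replicates:
        raise ValueError(f"{sample.sample_id}: no replicates at all")
    wanted = list(markers) if markers is not None else list(sample.replicates)

    deviation: dict[str, float | None] = {}
    status: dict[str, str] = {}
    for marker in wanted:
        reps = sample.replicates.get(marker, ())
        if not reps:
            deviation[marker] = None
            status[marker] = "missing"
        elif len(reps) == 1:
            deviation[marker] = None
            status[marker] = "pass"
        else:
            dev = abs(reps[0] - reps[1])
            deviation[marker] = dev
            status[marker] = "pass" if dev <= deviation_bound else "fail_deviation"

    concentration = sample.concentration_ng_ul
    return QCReport(
        sample_id=sample.sample_id,
        conversion_control_pass=sample.conversion_control_pass,
        concentration_ok=bool(concentration == concentration and concentration >= min_concentration),
        deviation=deviation,
        status=status,
        deviation_bound=deviation_bound,
    )


def collapse_replicates(
    sample: SampleRecord,
    report: QCReport,
    allow_single: bool = False,
) -> dict[str, float]:
    """Reduce duplicates to one value per marker (arithmetic mean).

    Markers that failed the deviation check or are missing are absent from
    the returned map; a failed conversion control empties it entirely.
    Singleton replicates pass through only under ``allow_single``.
    """
    if report.sample_id != sample.sample_id:
        raise ValueError("report does not belong to this sample")
    if not report.conversion_control_pass:
        return {}
    collapsed: dict[str, float] = {}
    for marker, stat in report.status.items():
        if stat != "pass":
            continue
        reps = sample.replicates.get(marker, ())
        if len(reps) == 1 and not allow_single:
            continue
        collapsed[marker] = float(sum(reps) / len(reps))
    return collapsed


def qc_frame(reports: Sequence[QCReport]) -> pd.DataFrame:
    """One row per (sample, marker), for delimited-text QC reports."""
    rows = []
    for rep in reports:
        for marker, stat in rep.status.items():
            rows.append(
                {
                    "sample_id": rep.sample_id,
                    "marker": marker,
                    "duplicate_deviation": rep.deviation[marker],
                    "status": stat,
                    "conversion_control": "pass" if rep.conversion_control_pass else "fail",
                    "concentration_ok": rep.concentration_ok,
                }
            )
    return pd.DataFrame(rows)
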