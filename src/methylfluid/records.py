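"""Sample records and delimited-text sample sheets.

A sample sheet has one row per stain with the columns::

    sample_id, true_composition, pretest_blood, pretest_saliva, pretest_sperm,
    NB21_rep1, NB21_rep2, ..., N27SE_rep1, N27SE_rep2,
    conversion_control, concentration_ng_ul

``true_composition`` is blank for casework samples and a ``+``-joined list of
``fluid:weight`` terms for simulated ones.  Missing replicate cells are left
empty; a marker with both cells empty was not assayed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .panel import MARKER_ORDER, PreTest, PreTestPanel

__all__ = ["SampleRecord", "records_to_frame", "frame_to_records",
           "write_sample_sheet", "read_sample_sheet"]


@dataclass
class SampleRecord:
    """Pre-test panel plus duplicate methylation values for one stain."""

    sample_id: str
    pretests: PreTestPanel
    replicates: dict[str, tuple[float, ...]]  # marker -> 1 or 2 values in [0, 100]
    conversion_control_pass: bool = True
    concentration_ng_ul: float = float("nan")
    true_composition: str = ""

    def __post_init__(self) -> None:
        for marker, reps in self.replicates.items():
            if not 1 <= len(reps) <= 2:
                raise ValueError(f"{marker}: expected 1 or 2 replicates, got {len(reps)}")
            for v in reps:
                if not 0 <= v <= 100:
                    raise ValueError(f"{marker}: methylation {v} outside [0, 100]")


def records_to_frame(records: Sequence[SampleRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row: dict = {
            "sample_id": rec.sample_id,
            "true_composition": rec.true_composition,
            "pretest_blood": rec.pretests.blood.value,
            "pretest_saliva": rec.pretests.saliva.value,
            "pretest_sperm": rec.pretests.sperm.value,
        }
        for marker in MARKER_ORDER:
            reps = rec.replicates.get(marker, ())
            row[f"{marker}_rep1"] = reps[0] if len(reps) >= 1 else math.nan
            row[f"{marker}_rep2"] = reps[1] if len(reps) >= 2 else math.nan
        row["conversion_control"] = "pass" if rec.conversion_control_pass else "fail"
        row["concentration_ng_ul"] = rec.concentration_ng_ul
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame) -> list[SampleRecord]:
    records = []
    for _, row in frame.iterrows():
        replicates: dict[str, tuple[float, ...]] = {}
        for marker in MARKER_ORDER:
            reps = [
                float(row[col])
                for col in (f"{marker}_rep1", f"{marker}_rep2")
                if col in row and pd.notna(row[col])
            ]
            if reps:
                replicates[marker] = tuple(reps)
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                pretests=PreTestPanel(
                    PreTest(row.get("pretest_blood", "not_done")),
                    PreTest(row.get("pretest_saliva", "not_done")),
                    PreTest(row.get("pretest_sperm", "not_done")),
                ),
                replicates=replicates,
                conversion_control_pass=row.get("conversion_control", "pass") == "pass",
                concentration_ng_ul=float(row.get("concentration_ng_ul", math.nan)),
                true_composition=str(row.get("true_composition", "") or ""),
            )
        )
    return records


def write_sample_sheet(records: Sequence[SampleRecord], path, sep: str = ",") -> None:
    records_to_frame(records).to_csv(path, sep=sep, index=False)


def read_sample_sheet(path, sep: str = ",") -> list[SampleRecord]:
    return frame_to_records(pd.read_csv(path, sep=sep))
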