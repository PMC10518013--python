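"""Inclusion/exclusion rules for raw Utstein-style record tables.

Adults (>= 18 y) with cardiogenic arrest are retained; records with missing,
negative, or implausibly long activity times (> 24 h) are dropped.  Rules are
applied in a fixed order — age, etiology, time validity — and each excluded
record is counted once, at its first failing rule.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

MAX_ACTIVITY_MINUTES = 1_440  # 24 h


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_excluded_age: int
    n_excluded_etiology: int
    n_excluded_time: int
    n_output: int

    def __post_init__(self) -> None:
        total = self.n_excluded_age + self.n_excluded_etiology + self.n_excluded_time
        if self.n_output != self.n_input - total:
            raise ValueError("exclusion counts do not reconcile with output size")

    def to_dict(self) -> dict[str, int]:
        return dataclasses.asdict(self)


def _time_rule_failures(df: pd.DataFrame, max_minutes: int) -> pd.Series:
    """Rows violating the time-validity rule (or lacking required fields).

    Fails a record when any present elapsed time is negative, an intervention
    was performed but its time is missing or < 1 min, any activity time exceeds
    ``max_minutes``, or age/etiology (required fields) are absent.
    """
    age = pd.to_numeric(df["age"], errors="coerce")
    etiology = df["etiology"].astype(object)
    fail = age.isna() | etiology.isna() | (etiology == "")

    call = pd.to_numeric(df["time_call_to_contact"], errors="coerce")
    hosp = pd.to_numeric(df["time_contact_to_hospital"], errors="coerce")
    fail |= call.isna() | (call < 0) | (call > max_minutes)
    fail |= hosp.isna() | (hosp < 0) | (hosp > max_minutes)

    for time_col, count_col in (
        ("time_contact_to_defib", "n_defib"),
        ("time_contact_to_drug", "n_drug_doses"),
    ):
        t = pd.to_numeric(df[time_col], errors="coerce")
        performed = pd.to_numeric(df[count_col], errors="coerce").fillna(0) > 0
        fail |= performed & (t.isna() | (t < 1) | (t > max_minutes))
        fail |= ~performed & t.notna() & ((t < 0) | (t > max_minutes))
    return fail


def apply_inclusion(
    table: pd.DataFrame, max_minutes: int = MAX_ACTIVITY_MINUTES
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the cohort rules; return the surviving table and a count report.

    Rule order: (1) age >= 18, (2) cardiogenic etiology, (3) time validity.
    Records missing age or etiology cannot be assessed by rules 1-2 and are
    excluded under the time/missing-data rule.
    """
    n_input = len(table)
    if n_input == 0:
        return table.copy(), FilterReport(0, 0, 0, 0, 0)

    age = pd.to_numeric(table["age"], errors="coerce")
    fail_age = age.notna() & (age < 18)
    etiology = table["etiology"].astype(object)
    fail_etio = etiology.notna() & (etiology != "") & (etiology != "cardiogenic")
    fail_time = _time_rule_failures(table, max_minutes)

    first = np.where(
        fail_age.to_numpy(), 1, np.where(fail_etio.to_numpy(), 2, np.where(fail_time.to_numpy(), 3, 0))
    )
    keep = first == 0
    report = FilterReport(
        n_input=n_input,
        n_excluded_age=int((first == 1).sum()),
        n_excluded_etiology=int((first == 2).sum()),
        n_excluded_time=int((first == 3).sum()),
        n_output=int(keep.sum()),
    )
    return table.loc[keep].copy(), report
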