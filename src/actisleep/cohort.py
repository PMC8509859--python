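"""Case/control/excluded assignment per psychiatric disorder.

Case status is defined from inpatient hospital diagnoses only: a participant
is a case for a disorder when their earliest in-range inpatient diagnosis is
on or before their accelerometry date.  To keep the control group free of
undiagnosed-in-hospital cases ("control contamination"), participants who
are not cases are excluded when the disorder appears in primary-care, death
or self-report records, or when their first inpatient diagnosis postdates
the accelerometry.  Everyone else is a control.

ICD-10 range membership is by 3-character prefix, so F32.1 falls in F32-F33.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass

import pandas as pd


class Source(enum.Enum):
    INPATIENT = "inpatient"
    PRIMARY_CARE = "primary_care"
    DEATH = "death"
    SELF_REPORT = "self_report"


class Status(enum.Enum):
    CASE = "case"
    CONTROL = "control"
    EXCLUDED = "excluded"


class Reason(enum.Enum):
    NONE = "none"
    NONINPATIENT_SOURCE = "noninpatient_source"
    FIRST_INPATIENT_POST_ACCEL = "first_inpatient_post_accel"


@dataclass(frozen=True)
class DisorderSpec:
    """A named disorder with its inclusive set of 3-character ICD-10 prefixes."""

    name: str
    icd_prefixes: frozenset[str]

    def contains(self, icd_code: str) -> bool:
        return icd_code[:3].upper() in self.icd_prefixes


def _prefix_range(lo: int, hi: int) -> frozenset[str]:
    return frozenset(f"F{i:02d}" for i in range(lo, hi + 1))


DISORDERS: dict[str, DisorderSpec] = {
    "schizophrenia_spectrum": DisorderSpec("schizophrenia_spectrum", _prefix_range(20, 29)),
    "bipolar_mania": DisorderSpec("bipolar_mania", _prefix_range(30, 31)),
    "major_depressive_disorder": DisorderSpec("major_depressive_disorder", _prefix_range(32, 33)),
    "anxiety": DisorderSpec("anxiety", _prefix_range(40, 41)),
}
ANY_DIAGNOSIS = "any_psychiatric_diagnosis"

_ICD_RE = re.compile(r"^[A-Z][0-9]{2}")

DIAGNOSIS_COLUMNS = ["participant_id", "icd_code", "source", "date"]


def validate_diagnoses(records: pd.DataFrame) -> pd.DataFrame:
    """Validate a diagnosis table (participant_id, icd_code, source, date).

    Dates may be missing only for self-report records; a malformed ICD code
    is a hard error.  Returns the table with parsed dates and Source enums.
    """
    df = records.copy()
    bad = ~df["icd_code"].astype(str).str.match(_ICD_RE)
    if bad.any():
        raise ValueError(f"malformed ICD code(s): {sorted(df.loc[bad, 'icd_code'].unique())}")
    df["source"] = df["source"].map(lambda s: Source(str(s).lower()))
    df["date"] = pd.to_datetime(df["date"], errors="raise").dt.date
    undated = df["date"].isna() & (df["source"] != Source.SELF_REPORT)
    if undated.any():
        raise ValueError("undated record(s) from a dated source")
    return df


def assign(
    records: pd.DataFrame,
    accel_dates: pd.Series,
    spec: DisorderSpec,
) -> pd.DataFrame:
    """Assign case/control/excluded status for one disorder.

    ``records`` is a validated diagnosis table; ``accel_dates`` maps
    participant_id -> accelerometry date for every participant in the
    cohort.  Precedence: a pre-accelerometry inpatient diagnosis makes a
    case outright; otherwise a post-accelerometry first inpatient diagnosis
    excludes; otherwise any in-range primary-care/death/self-report record
    excludes (undated self-reports count — "preexisting" cannot be verified
    without a date); otherwise control.
    """
    in_range = records[records["icd_code"].map(spec.contains)]
    rows = []
    for pid, accel_date in accel_dates.items():
        mine = in_range[in_range["participant_id"] == pid]
        inpt = mine[mine["source"] == Source.INPATIENT]
        status, reason = Status.CONTROL, Reason.NONE
        if len(inpt):
            first = min(inpt["date"])
            if first <= accel_date:
                status = Status.CASE
            else:
                status, reason = Status.EXCLUDED, Reason.FIRST_INPATIENT_POST_ACCEL
        if status is not Status.CASE and reason is Reason.NONE:
            if len(mine[mine["source"] != Source.INPATIENT]):
                status, reason = Status.EXCLUDED, Reason.NONINPATIENT_SOURCE
        rows.append(
            {
                "participant_id": pid,
                "disorder": spec.name,
                "status": status.value,
                "reason": reason.value,
            }
        )
    return pd.DataFrame(rows)


def any_diagnosis(assignments: pd.DataFrame) -> pd.DataFrame:
    """Composite "any psychiatric diagnosis" exposure from per-disorder assignments.

    Case for any disorder -> case; otherwise excluded for any disorder ->
    excluded; otherwise control.
    """
    def collapse(group: pd.DataFrame) -> pd.Series:
        statuses = set(group["status"])
        if Status.CASE.value in statuses:
            status, reason = Status.CASE.value, Reason.NONE.value
        elif Status.EXCLUDED.value in statuses:
            status = Status.EXCLUDED.value
            reason = group.loc[group["status"] == Status.EXCLUDED.value, "reason"].iloc[0]
        else:
            status, reason = Status.CONTROL.value, Reason.NONE.value
        return pd.Series({"disorder": ANY_DIAGNOSIS, "status": status, "reason": reason})

    out = (
        assignments.groupby("participant_id", sort=True)
        .apply(collapse, include_groups=False)
        .reset_index()
    )
    return out[["participant_id", "disorder", "status", "reason"]]


def build_cohort(
    records: pd.DataFrame,
    accel_dates: pd.Series,
    disorders: dict[str, DisorderSpec] = DISORDERS,
) -> pd.DataFrame:
    """Assignments for every disorder plus the composite exposure, long format."""
    records = validate_diagnoses(records)
    per = [assign(records, accel_dates, spec) for spec in disorders.values()]
    tall = pd.concat(per, ignore_index=True)
    return pd.concat([tall, any_diagnosis(tall)], ignore_index=True)


def exposure_matrix(assignments: pd.DataFrame) -> pd.DataFrame:
    """Wide 0/1 exposure matrix indexed by participant; excluded -> NaN.

    One column per disorder (and the composite); the association battery
    drops NaN rows per exposure, which implements the per-disorder
    exclusions.
    """
    wide = assignments.pivot(index="participant_id", columns="disorder", values="status")
    mapping = {Status.CASE.value: 1.0, Status.CONTROL.value: 0.0,
               Status.EXCLUDED.value: float("nan")}
    out = wide.apply(lambda col: col.map(mapping)).astype(float)
    out.columns.name = None
    cols = [*DISORDERS.keys(), ANY_DIAGNOSIS]
    return out[[c for c in cols if c in out.columns]]
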