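"""Patient vital-sign data model, table I/O and compliance computation.

A monitored patient self-measures three values once daily: weight (kg),
transcutaneous oxygen saturation (SpO2, %) and heart rate (bpm).  This module
defines the in-memory containers for those records, reads and writes the
delimited-text interchange format, and computes measurement compliance
(the fraction of calendar days with a complete three-value triplet, which
must reach a threshold -- 75% by convention -- for a patient to count as
compliant).
"""

from __future__ import annotations

import datetime as dt
import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "DailyVitals",
    "PatientRecord",
    "ComplianceSummary",
    "FlaggedCell",
    "RejectedRow",
    "ParsedVitals",
    "VitalsFormatError",
    "VitalsDataError",
    "VITALS_COLUMNS",
    "WEIGHT_RANGE",
    "SPO2_RANGE",
    "HR_RANGE",
    "COMPLIANCE_THRESHOLD",
    "read_vitals_table",
    "write_vitals_table",
    "compute_compliance",
    "derive_baseline_weight",
]

# Interchange format: CSV with this exact header, ISO-8601 dates, empty
# cell = missing value.
VITALS_COLUMNS = ("patient_id", "date", "weight_kg", "spo2_pct", "hr_bpm")

# Physiologically plausible ranges; values outside are flagged as invalid
# and treated as missing (self-measurement devices do produce garbage).
WEIGHT_RANGE = (0.0, 400.0)   # exclusive bounds, kg
SPO2_RANGE = (50.0, 100.0)    # inclusive bounds, %
HR_RANGE = (20.0, 300.0)      # inclusive bounds, bpm

#: Minimum fraction of complete measurement days for study inclusion.
COMPLIANCE_THRESHOLD = 0.75


class VitalsFormatError(ValueError):
    """The table cannot be interpreted at all (e.g. a column is missing)."""


class VitalsDataError(ValueError):
    """The table parses but violates a data invariant (e.g. duplicate days)."""


def _weight_ok(v: float) -> bool:
    return WEIGHT_RANGE[0] < v < WEIGHT_RANGE[1]


def _spo2_ok(v: float) -> bool:
    return SPO2_RANGE[0] <= v <= SPO2_RANGE[1]


def _hr_ok(v: float) -> bool:
    return HR_RANGE[0] <= v <= HR_RANGE[1]


@dataclass(frozen=True, slots=True)
class DailyVitals:
    """One day's self-measurement triplet for one patient.

    Any of the three values may be ``None`` (not measured, or measured but
    rejected as implausible upstream).  Stored values always satisfy the
    plausibility ranges; constructing an out-of-range value raises.
    """

    patient_id: str
    day: dt.date
    weight: float | None = None
    spo2: float | None = None
    heart_rate: float | None = None

    def __post_init__(self) -> None:
        if self.weight is not None and not _weight_ok(self.weight):
            raise ValueError(f"weight {self.weight} kg outside {WEIGHT_RANGE}")
        if self.spo2 is not None and not _spo2_ok(self.spo2):
            raise ValueError(f"spo2 {self.spo2}% outside {SPO2_RANGE}")
        if self.heart_rate is not None and not _hr_ok(self.heart_rate):
            raise ValueError(f"heart rate {self.heart_rate} bpm outside {HR_RANGE}")

    @property
    def is_complete(self) -> bool:
        """True when all three values were recorded."""
        return (
            self.weight is not None
            and self.spo2 is not None
            and self.heart_rate is not None
        )


@dataclass(frozen=True)
class PatientRecord:
    """A patient's whole monitored time series.

    ``vitals`` is strictly ascending by day, at most one entry per day, and
    every day lies inside ``[enrollment_day, followup_end]``.
    """

    patient_id: str
    enrollment_day: dt.date
    followup_end: dt.date
    vitals: tuple[DailyVitals, ...]

    def __post_init__(self) -> None:
        if self.followup_end < self.enrollment_day:
            raise ValueError("followup_end precedes enrollment_day")
        prev: dt.date | None = None
        for v in self.vitals:
            if v.patient_id != self.patient_id:
                raise ValueError(
                    f"vitals for {v.patient_id!r} inside record {self.patient_id!r}"
                )
            if not (self.enrollment_day <= v.day <= self.followup_end):
                raise ValueError(f"vitals day {v.day} outside follow-up window")
            if prev is not None and v.day <= prev:
                raise ValueError(f"vitals not strictly ascending at {v.day}")
            prev = v.day

    def by_day(self) -> dict[dt.date, DailyVitals]:
        return {v.day: v for v in self.vitals}

    @property
    def baseline_weight(self) -> float:
        return derive_baseline_weight(self)


@dataclass(frozen=True, slots=True)
class ComplianceSummary:
    """Measurement compliance over a window of calendar days."""

    n_days_observed: int
    n_days_complete: int
    fraction_complete: float
    is_compliant: bool

    def __post_init__(self) -> None:
        if self.n_days_complete > self.n_days_observed:
            raise ValueError("complete days exceed observed days")


@dataclass(frozen=True, slots=True)
class FlaggedCell:
    """An implausible value found while reading: kept in the report, the
    cell itself treated as missing."""

    patient_id: str
    day: dt.date
    column: str
    value: float


@dataclass(frozen=True, slots=True)
class RejectedRow:
    """A row dropped at read time (unparseable date), with its source line."""

    row_index: int
    reason: str


@dataclass(frozen=True)
class ParsedVitals:
    """Outcome of reading a vitals table: records plus a parse report."""

    records: tuple[PatientRecord, ...]
    flagged_cells: tuple[FlaggedCell, ...] = ()
    rejected_rows: tuple[RejectedRow, ...] = ()

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _clean_value(raw, ok) -> tuple[float | None, bool]:
    """Return (value-or-None, flagged?)."""
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None, False
    v = float(raw)
    if not ok(v):
        return None, True
    return v, False


def read_vitals_table(
    path,
    *,
    delimiter: str = ",",
) -> ParsedVitals:
    """Read a delimited vitals table into :class:`PatientRecord` objects.

    The file must carry the columns ``patient_id,date,weight_kg,spo2_pct,
    hr_bpm``.  Empty cells are missing values.  Rows whose date does not
    parse are rejected and reported; physiologically implausible cells are
    flagged and treated as missing rather than dropped.  Duplicate
    ``(patient_id, date)`` pairs are a data error.
    """
    df = pd.read_csv(path, sep=delimiter, dtype={"patient_id": str})
    missing = [c for c in VITALS_COLUMNS if c not in df.columns]
    if missing:
        raise VitalsFormatError(f"missing mandatory column(s): {', '.join(missing)}")

    parsed_dates = pd.to_datetime(df["date"], errors="coerce", format="ISO8601")
    rejected = tuple(
        RejectedRow(int(i), f"unparseable date {df['date'].iloc[i]!r}")
        for i in df.index[parsed_dates.isna()]
    )
    df = df[parsed_dates.notna()].copy()
    df["date"] = parsed_dates[parsed_dates.notna()].dt.date

    dupes = df[df.duplicated(subset=["patient_id", "date"], keep=False)]
    if not dupes.empty:
        keys = sorted(
            {f"{pid}, {day.isoformat()}" for pid, day in zip(dupes["patient_id"], dupes["date"])}
        )
        raise VitalsDataError(f"duplicate (patient, day) entries: {'; '.join(keys)}")

    flagged: list[FlaggedCell] = []
    records: list[PatientRecord] = []
    for pid, group in df.groupby("patient_id", sort=True):
        group = group.sort_values("date")
        vitals = []
        for row in group.itertuples(index=False):
            day = row.date
            w, fw = _clean_value(row.weight_kg, _weight_ok)
            s, fs = _clean_value(row.spo2_pct, _spo2_ok)
            h, fh = _clean_value(row.hr_bpm, _hr_ok)
            for bad, col, raw in (
                (fw, "weight_kg", row.weight_kg),
                (fs, "spo2_pct", row.spo2_pct),
                (fh, "hr_bpm", row.hr_bpm),
            ):
                if bad:
                    flagged.append(FlaggedCell(str(pid), day, col, float(raw)))
            vitals.append(
                DailyVitals(str(pid), day, weight=w, spo2=s, heart_rate=h)
            )
        records.append(
            PatientRecord(
                patient_id=str(pid),
                enrollment_day=vitals[0].day,
                followup_end=vitals[-1].day,
                vitals=tuple(vitals),
            )
        )
    return ParsedVitals(tuple(records), tuple(flagged), tuple(rejected))


def write_vitals_table(records: Iterable[PatientRecord], path, *, delimiter: str = ",") -> None:
    """Write records in the interchange CSV format (round-trips with
    :func:`read_vitals_table` on valid data)."""
    rows = [
        {
            "patient_id": v.patient_id,
            "date": v.day.isoformat(),
            "weight_kg": v.weight,
            "spo2_pct": v.spo2,
            "hr_bpm": v.heart_rate,
        }
        for rec in records
        for v in rec.vitals
    ]
    pd.DataFrame(rows, columns=list(VITALS_COLUMNS)).to_csv(path, sep=delimiter, index=False)


def compute_compliance(
    record: PatientRecord,
    window: tuple[dt.date, dt.date] | None = None,
    threshold: float = COMPLIANCE_THRESHOLD,
) -> ComplianceSummary:
    """Compliance over ``window`` (inclusive date pair; defaults to the whole
    follow-up).

    The denominator is the number of calendar days in the window -- days with
    no record at all count against compliance -- and a day is complete only
    when all three values are present.
    """
    if window is None:
        window = (record.enrollment_day, record.followup_end)
    start, end = window
    if end < start:
        raise ValueError(f"empty compliance window {start}..{end}")
    n_calendar = (end - start).days + 1
    in_window = [v for v in record.vitals if start <= v.day <= end]
    n_complete = sum(v.is_complete for v in in_window)
    fraction = n_complete / n_calendar
    return ComplianceSummary(
        n_days_observed=len(in_window),
        n_days_complete=n_complete,
        fraction_complete=fraction,
        is_compliant=fraction >= threshold,
    )


def derive_baseline_weight(record: PatientRecord, method: str = "first") -> float:
    """Reference weight against which absolute weight gain is judged.

    ``method="first"`` (default): the first non-missing weight at or after
    enrollment.  ``method="median7"``: median of the non-missing weights in
    the first 7 calendar days of follow-up.
    """
    if method == "first":
        for v in record.vitals:
            if v.weight is not None:
                return v.weight
        raise VitalsDataError(f"patient {record.patient_id!r} has no recorded weight")
    if method == "median7":
        cutoff = record.enrollment_day + dt.timedelta(days=6)
        week = sorted(
            v.weight for v in record.vitals if v.day <= cutoff and v.weight is not None
        )
        if not week:
            # fall back to the first weight ever recorded
            return derive_baseline_weight(record, method="first")
        n = len(week)
        mid = n // 2
        return week[mid] if n % 2 else (week[mid - 1] + week[mid]) / 2.0
    raise ValueError(f"unknown baseline method {method!r}")
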