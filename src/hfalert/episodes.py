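"""Alert adjudication: from daily firings to labelled clinical episodes.

A patient whose measurements stay abnormal fires the alert engine on
several consecutive days; clinically that is one event, handled by one
call-back.  This module merges runs of fired days into episodes, labels
each episode *confirmed AHF* or *unconfirmed* by matching it against
ground-truth events (from the simulator, or an external label table for
real data), and produces the usual audit summaries: alert-type breakdown
and time from enrollment to alert.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import DailyAlertDecision

__all__ = [
    "AlertEpisode",
    "GroundTruthEvent",
    "EVENT_TYPES",
    "UNCONFIRMED_CAUSES",
    "DEFAULT_GAP_DAYS",
    "DEFAULT_MATCH_WINDOW_DAYS",
    "merge_firings",
    "label_episodes",
    "summarize_alerts",
    "episodes_to_frame",
    "read_events_table",
    "write_events_table",
]

EVENT_TYPES = ("AHF", "arrhythmia", "infection", "measurement_error")
UNCONFIRMED_CAUSES = (
    "arrhythmia",
    "inaccurate_measurement",
    "bacterial_pneumonia",
    "covid19",
    "other",
)

# Firings this close (in calendar days) are one clinical episode: alerts are
# resolved by a call within ~72 h, so a 3-day refractory grouping mirrors
# the care workflow.
DEFAULT_GAP_DAYS = 3
# Episode/event overlap slack on each side, for the same workflow-latency
# reason.
DEFAULT_MATCH_WINDOW_DAYS = 3

# ground-truth event type -> adjudicated cause of an unconfirmed alert
_CAUSE_OF_EVENT = {
    "arrhythmia": "arrhythmia",
    "measurement_error": "inaccurate_measurement",
    "infection": "bacterial_pneumonia",
}


@dataclass(frozen=True)
class AlertEpisode:
    """A maximal run of alert firings, optionally adjudicated."""

    patient_id: str
    onset: dt.date
    offset: dt.date
    criteria_types: frozenset[str]
    label: Literal["confirmed_AHF", "unconfirmed"] | None = None
    unconfirmed_cause: str | None = None
    days_since_enrollment: int | None = None

    def __post_init__(self) -> None:
        if self.offset < self.onset:
            raise ValueError("episode offset precedes onset")
        if self.unconfirmed_cause is not None and self.label != "unconfirmed":
            raise ValueError("a cause requires label == 'unconfirmed'")
        if self.unconfirmed_cause is not None and self.unconfirmed_cause not in UNCONFIRMED_CAUSES:
            raise ValueError(f"unknown cause {self.unconfirmed_cause!r}")


@dataclass(frozen=True, slots=True)
class GroundTruthEvent:
    """A simulated (or externally supplied) clinical episode."""

    patient_id: str
    event_type: str
    onset: dt.date
    offset: dt.date

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if self.offset < self.onset:
            raise ValueError("event offset precedes onset")


def merge_firings(
    decisions: Sequence[DailyAlertDecision],
    gap_days: int = DEFAULT_GAP_DAYS,
    *,
    patient_id: str = "",
    enrollment_day: dt.date | None = None,
) -> list[AlertEpisode]:
    """Group fired days into episodes.

    Two successive fired days belong to the same episode when they are at
    most ``gap_days`` calendar days apart; with ``gap_days=0`` every fired
    day is its own episode.  ``criteria_types`` is the union over the run.
    """
    if gap_days < 0:
        raise ValueError("gap_days must be >= 0")
    fired = [d for d in decisions if d.fired]
    episodes: list[AlertEpisode] = []
    run: list[DailyAlertDecision] = []

    def flush() -> None:
        if not run:
            return
        onset = run[0].day
        episodes.append(
            AlertEpisode(
                patient_id=patient_id,
                onset=onset,
                offset=run[-1].day,
                criteria_types=frozenset().union(*(d.criteria_types for d in run)),
                days_since_enrollment=(
                    (onset - enrollment_day).days if enrollment_day is not None else None
                ),
            )
        )

    for d in fired:
        if run and (d.day - run[-1].day).days > gap_days:
            flush()
            run = []
        run.append(d)
    flush()
    return episodes


def _overlaps(ep: AlertEpisode, ev: GroundTruthEvent, slack: int) -> bool:
    pad = dt.timedelta(days=slack)
    return ep.onset - pad <= ev.offset and ev.onset <= ep.offset + pad


def label_episodes(
    episodes: Iterable[AlertEpisode],
    truth: Iterable[GroundTruthEvent],
    match_window_days: int = DEFAULT_MATCH_WINDOW_DAYS,
) -> list[AlertEpisode]:
    """Adjudicate each episode against ground truth.

    An episode overlapping an AHF event (padded by ``match_window_days`` on
    each side) is ``confirmed_AHF``; AHF wins over any simultaneously
    overlapping non-AHF event, since catching a true decompensation is the
    point of the system.  Otherwise the episode is ``unconfirmed`` with the
    cause of the earliest overlapping non-AHF event, or ``other`` when
    nothing overlaps.
    """
    by_patient: dict[str, list[GroundTruthEvent]] = {}
    for ev in truth:
        by_patient.setdefault(ev.patient_id, []).append(ev)

    out: list[AlertEpisode] = []
    for ep in episodes:
        events = by_patient.get(ep.patient_id, [])
        hits = [ev for ev in events if _overlaps(ep, ev, match_window_days)]
        if any(ev.event_type == "AHF" for ev in hits):
            out.append(replace(ep, label="confirmed_AHF", unconfirmed_cause=None))
            continue
        cause = "other"
        for ev in sorted(hits, key=lambda e: e.onset):
            cause = _CAUSE_OF_EVENT[ev.event_type]
            break
        out.append(replace(ep, label="unconfirmed", unconfirmed_cause=cause))
    return out


def _timing_row(days: list[int]) -> dict:
    if not days:
        return {"n": 0, "median": np.nan, "iqr_low": np.nan, "iqr_high": np.nan}
    arr = np.asarray(days, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return {"n": len(days), "median": med, "iqr_low": q1, "iqr_high": q3}


def summarize_alerts(episodes: Sequence[AlertEpisode]) -> dict[str, pd.DataFrame]:
    """Audit summary of a labelled episode set.

    Returns ``{"types": ..., "timing": ...}`` where *types* counts episodes
    by criteria combination ("+"-joined families) with percentages per
    label column (all / confirmed / unconfirmed), and *timing* holds the
    median and IQR of days from enrollment to episode onset, overall and
    per label.  Empty input yields empty tables.
    """
    labelled = list(episodes)
    groups = {
        "all": labelled,
        "confirmed_AHF": [e for e in labelled if e.label == "confirmed_AHF"],
        "unconfirmed": [e for e in labelled if e.label == "unconfirmed"],
    }

    combos = sorted({"+".join(sorted(e.criteria_types)) for e in labelled})
    type_rows = []
    for combo in combos:
        row: dict = {"criteria": combo}
        for name, eps in groups.items():
            n = sum("+".join(sorted(e.criteria_types)) == combo for e in eps)
            row[f"n_{name}"] = n
            row[f"pct_{name}"] = 100.0 * n / len(eps) if eps else np.nan
        type_rows.append(row)
    types = pd.DataFrame(type_rows)

    timing_rows = []
    for name, eps in groups.items():
        days = [e.days_since_enrollment for e in eps if e.days_since_enrollment is not None]
        timing_rows.append({"group": name, **_timing_row(days)})
    timing = pd.DataFrame(timing_rows)
    return {"types": types, "timing": timing}


def episodes_to_frame(episodes: Iterable[AlertEpisode]) -> pd.DataFrame:
    """Interchange table: ``patient_id,onset,offset,criteria_types,label,
    unconfirmed_cause,days_since_enrollment``."""
    rows = [
        {
            "patient_id": e.patient_id,
            "onset": e.onset.isoformat(),
            "offset": e.offset.isoformat(),
            "criteria_types": "+".join(sorted(e.criteria_types)),
            "label": e.label or "",
            "unconfirmed_cause": e.unconfirmed_cause or "",
            "days_since_enrollment": e.days_since_enrollment,
        }
        for e in episodes
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "onset",
            "offset",
            "criteria_types",
            "label",
            "unconfirmed_cause",
            "days_since_enrollment",
        ],
    )


def read_events_table(path) -> list[GroundTruthEvent]:
    """Read the ground-truth events CSV
    (``patient_id,event_type,onset,offset``, ISO dates)."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = ["patient_id", "event_type", "onset", "offset"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"events table missing column(s): {', '.join(missing)}")
    return [
        GroundTruthEvent(
            patient_id=row.patient_id,
            event_type=row.event_type,
            onset=dt.date.fromisoformat(row.onset),
            offset=dt.date.fromisoformat(row.offset),
        )
        for row in df.itertuples(index=False)
    ]


def write_events_table(events: Iterable[GroundTruthEvent], path) -> None:
    rows = [
        {
            "patient_id": e.patient_id,
            "event_type": e.event_type,
            "onset": e.onset.isoformat(),
            "offset": e.offset.isoformat(),
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=["patient_id", "event_type", "onset", "offset"]).to_csv(
        path, index=False
    )
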