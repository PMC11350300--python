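"""Rule-based acute-heart-failure (AHF) alert engine.

The alert algorithm evaluates each day's self-measurements against a fixed
clinical rule set with two firing paths:

* **major** -- a single severe abnormality suffices: heart rate above
  110 bpm, SpO2 below 90%, weight gain of at least 4 kg over the baseline
  weight, or weight gain of at least 4 kg within a 4-day window;
* **minor** -- at least two concurrent milder abnormalities: heart rate
  above 90 bpm, SpO2 below 92%, or weight gain of at least 2 kg within the
  4-day window.

Each fired day carries the criterion *families* that contributed
(``weight_gain``, ``loss_of_oxygen``, ``increased_heart_rate``), matching
how alerts are traditionally categorised in telemonitoring audits.  The
engine reports every firing day; grouping runs of firings into clinical
episodes is the adjudication layer's job.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

from .cohort import DailyVitals, PatientRecord, derive_baseline_weight

__all__ = [
    "AlertRuleConfig",
    "CriterionFlags",
    "DailyAlertDecision",
    "WEIGHT_GAIN",
    "LOSS_OF_OXYGEN",
    "INCREASED_HEART_RATE",
    "weight_gain_in_window",
    "evaluate_criteria",
    "decide_alert",
    "scan_patient",
    "decisions_to_frame",
]

# Criterion family tokens, as reported in alert-type taxonomies.
WEIGHT_GAIN = "weight_gain"
LOSS_OF_OXYGEN = "loss_of_oxygen"
INCREASED_HEART_RATE = "increased_heart_rate"


@dataclass(frozen=True)
class AlertRuleConfig:
    """Thresholds and windows of the alert algorithm.

    Defaults are the clinically predefined values: HR > 110 / > 90 bpm,
    SpO2 < 90 / < 92 %, weight gain >= 4 / >= 2 kg, 4-day weight window,
    two minor criteria required.

    ``minor_weight_window_days`` overrides the window length for the minor
    weight criterion only (some protocol descriptions use a 2-day minor
    window); ``None`` means use ``weight_window_days`` for both paths.
    ``weight_gain_mode`` selects how the windowed gain is computed:
    ``"max_pairwise"`` (default) takes the maximum gain of today's weight
    over any available prior weight inside the window, which stays sensitive
    on sparse records; ``"endpoint"`` compares strictly against the weight
    exactly ``window`` days earlier.  ``weight_comparison`` sets whether
    weight-gain thresholds are met at equality (``"ge"``, default) or only
    strictly above (``"gt"``); heart-rate and SpO2 comparisons are always
    strict, per their clinical definitions ("above 110 bpm", "< 90%").
    """

    hr_major: float = 110.0
    hr_minor: float = 90.0
    spo2_major: float = 90.0
    spo2_minor: float = 92.0
    weight_major_gain: float = 4.0
    weight_minor_gain: float = 2.0
    weight_window_days: int = 4
    minor_criteria_required: int = 2
    minor_weight_window_days: int | None = None
    weight_gain_mode: Literal["max_pairwise", "endpoint"] = "max_pairwise"
    weight_comparison: Literal["ge", "gt"] = "ge"

    def __post_init__(self) -> None:
        if not self.hr_minor < self.hr_major:
            raise ValueError("hr_minor must be below hr_major")
        if not self.spo2_major < self.spo2_minor:
            raise ValueError("spo2_major must be below spo2_minor")
        if not self.weight_minor_gain < self.weight_major_gain:
            raise ValueError("weight_minor_gain must be below weight_major_gain")
        if self.weight_window_days < 1:
            raise ValueError("weight_window_days must be >= 1")
        if self.minor_weight_window_days is not None and self.minor_weight_window_days < 1:
            raise ValueError("minor_weight_window_days must be >= 1")
        if self.minor_criteria_required < 1:
            raise ValueError("minor_criteria_required must be >= 1")
        if self.weight_gain_mode not in ("max_pairwise", "endpoint"):
            raise ValueError(f"unknown weight_gain_mode {self.weight_gain_mode!r}")
        if self.weight_comparison not in ("ge", "gt"):
            raise ValueError(f"unknown weight_comparison {self.weight_comparison!r}")

    @property
    def minor_window(self) -> int:
        return self.minor_weight_window_days or self.weight_window_days

    def _gain_met(self, gain: float | None, threshold: float) -> bool:
        if gain is None:
            return False
        return gain >= threshold if self.weight_comparison == "ge" else gain > threshold

    @classmethod
    def from_json(cls, path) -> "AlertRuleConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
            fh.write("\n")


@dataclass(frozen=True, slots=True)
class CriterionFlags:
    """Which individual rule clauses hold on a given day.

    Severity is nested: a major abnormality implies its minor counterpart
    (``hr_major => hr_minor`` etc.), which keeps the flag set monotone in
    the measurements.
    """

    hr_major: bool = False
    hr_minor: bool = False
    spo2_major: bool = False
    spo2_minor: bool = False
    weight_major_baseline: bool = False
    weight_major_window: bool = False
    weight_minor_window: bool = False

    def __post_init__(self) -> None:
        if self.hr_major and not self.hr_minor:
            raise ValueError("hr_major implies hr_minor")
        if self.spo2_major and not self.spo2_minor:
            raise ValueError("spo2_major implies spo2_minor")
        if self.weight_major_window and not self.weight_minor_window:
            raise ValueError("weight_major_window implies weight_minor_window")

    @property
    def any_major(self) -> bool:
        return (
            self.hr_major
            or self.spo2_major
            or self.weight_major_baseline
            or self.weight_major_window
        )


@dataclass(frozen=True, slots=True)
class DailyAlertDecision:
    """The engine's verdict for one observed day."""

    day: dt.date
    flags: CriterionFlags
    fired: bool
    path: Literal["major", "minor", "none"]
    criteria_types: frozenset[str]

    def __post_init__(self) -> None:
        if self.fired != (self.path != "none"):
            raise ValueError("fired must mirror path != none")
        if self.fired != bool(self.criteria_types):
            raise ValueError("criteria_types must be nonempty iff fired")


def weight_gain_in_window(
    record: PatientRecord,
    day: dt.date,
    window_days: int,
    *,
    mode: str = "max_pairwise",
    _by_day: Mapping[dt.date, DailyVitals] | None = None,
) -> float | None:
    """Weight gain on ``day`` relative to the preceding ``window_days`` days.

    ``max_pairwise`` returns ``max_k (weight(day) - weight(day-k))`` for
    k = 1..window over days where a weight exists; ``endpoint`` returns
    ``weight(day) - weight(day - window_days)`` only.  ``None`` when today's
    weight, or every needed prior weight, is missing.
    """
    vmap = _by_day if _by_day is not None else record.by_day()
    today = vmap.get(day)
    if today is None or today.weight is None:
        return None
    if mode == "endpoint":
        ref = vmap.get(day - dt.timedelta(days=window_days))
        if ref is None or ref.weight is None:
            return None
        return today.weight - ref.weight
    if mode != "max_pairwise":
        raise ValueError(f"unknown weight gain mode {mode!r}")
    best: float | None = None
    for k in range(1, window_days + 1):
        prior = vmap.get(day - dt.timedelta(days=k))
        if prior is None or prior.weight is None:
            continue
        gain = today.weight - prior.weight
        if best is None or gain > best:
            best = gain
    return best


def _evaluate(
    vmap: Mapping[dt.date, DailyVitals],
    baseline_weight: float | None,
    day: dt.date,
    config: AlertRuleConfig,
    record: PatientRecord,
) -> CriterionFlags:
    v = vmap.get(day)
    hr = v.heart_rate if v is not None else None
    spo2 = v.spo2 if v is not None else None
    weight = v.weight if v is not None else None

    hr_major = hr is not None and hr > config.hr_major
    hr_minor = hr is not None and hr > config.hr_minor
    spo2_major = spo2 is not None and spo2 < config.spo2_major
    spo2_minor = spo2 is not None and spo2 < config.spo2_minor

    major_gain = weight_gain_in_window(
        record, day, config.weight_window_days, mode=config.weight_gain_mode, _by_day=vmap
    )
    if config.minor_window == config.weight_window_days:
        minor_gain = major_gain
    else:
        minor_gain = weight_gain_in_window(
            record, day, config.minor_window, mode=config.weight_gain_mode, _by_day=vmap
        )
    baseline_gain = (
        weight - baseline_weight
        if weight is not None and baseline_weight is not None
        else None
    )

    weight_major_window = config._gain_met(major_gain, config.weight_major_gain)
    weight_minor_window = (
        config._gain_met(minor_gain, config.weight_minor_gain) or weight_major_window
    )
    return CriterionFlags(
        hr_major=hr_major,
        hr_minor=hr_minor,
        spo2_major=spo2_major,
        spo2_minor=spo2_minor,
        weight_major_baseline=config._gain_met(baseline_gain, config.weight_major_gain),
        weight_major_window=weight_major_window,
        weight_minor_window=weight_minor_window,
    )


def evaluate_criteria(
    record: PatientRecord, day: dt.date, config: AlertRuleConfig | None = None
) -> CriterionFlags:
    """Evaluate every rule clause for one day of one patient's record.

    A missing measurement leaves its flags False: the rule set never fires
    on absent data.
    """
    config = config or AlertRuleConfig()
    if not (record.enrollment_day <= day <= record.followup_end):
        raise ValueError(f"day {day} outside follow-up of {record.patient_id!r}")
    try:
        baseline = derive_baseline_weight(record)
    except Exception:
        baseline = None
    return _evaluate(record.by_day(), baseline, day, config, record)


def decide_alert(
    flags: CriterionFlags,
    config: AlertRuleConfig | None = None,
    day: dt.date | None = None,
) -> DailyAlertDecision:
    """Combine criterion flags into the day's firing decision.

    Any major flag fires the major path on its own; otherwise the minor path
    fires when at least ``minor_criteria_required`` of the three minor
    families (heart rate, oxygen, windowed weight gain) hold concurrently.
    ``criteria_types`` lists the families that contributed to the firing
    path.
    """
    config = config or AlertRuleConfig()
    day = day or dt.date.min
    if flags.any_major:
        types = set()
        if flags.weight_major_baseline or flags.weight_major_window:
            types.add(WEIGHT_GAIN)
        if flags.spo2_major:
            types.add(LOSS_OF_OXYGEN)
        if flags.hr_major:
            types.add(INCREASED_HEART_RATE)
        return DailyAlertDecision(day, flags, True, "major", frozenset(types))
    minor_families = {
        INCREASED_HEART_RATE: flags.hr_minor,
        LOSS_OF_OXYGEN: flags.spo2_minor,
        WEIGHT_GAIN: flags.weight_minor_window,
    }
    held = frozenset(f for f, on in minor_families.items() if on)
    if len(held) >= config.minor_criteria_required:
        return DailyAlertDecision(day, flags, True, "minor", held)
    return DailyAlertDecision(day, flags, False, "none", frozenset())


def scan_patient(
    record: PatientRecord, config: AlertRuleConfig | None = None
) -> list[DailyAlertDecision]:
    """Run the alert algorithm over every observed day, in date order."""
    config = config or AlertRuleConfig()
    vmap = record.by_day()
    try:
        baseline = derive_baseline_weight(record)
    except Exception:
        baseline = None
    out = []
    for v in record.vitals:
        flags = _evaluate(vmap, baseline, v.day, config, record)
        out.append(decide_alert(flags, config, day=v.day))
    return out


def decisions_to_frame(decisions_by_patient: Mapping[str, Sequence[DailyAlertDecision]]):
    """Flatten per-patient decisions into the interchange table
    ``patient_id,date,fired,path,criteria_types`` (types joined by ``+``)."""
    import pandas as pd

    rows = [
        {
            "patient_id": pid,
            "date": d.day.isoformat(),
            "fired": d.fired,
            "path": d.path,
            "criteria_types": "+".join(sorted(d.criteria_types)),
        }
        for pid, decisions in decisions_by_patient.items()
        for d in decisions
    ]
    return pd.DataFrame(rows, columns=["patient_id", "date", "fired", "path", "criteria_types"])
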