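"""Patient-level diagnostic performance of the alerting system.

The unit of analysis is the patient, not the alert: a patient counts as
*alerted* when at least one episode fired during follow-up, and as a *true
AHF* case when a genuine decompensation occurred.  From those two axes the
usual 2x2 confusion matrix and its derived metrics (sensitivity,
specificity, PPV, NPV) are computed, both globally and per criterion
family, alongside 2x2 association tests and time-to-first-alert order
statistics.

Undefined ratios (empty denominator) are reported as ``None``/NaN, never
coerced to zero.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .engine import INCREASED_HEART_RATE, LOSS_OF_OXYGEN, WEIGHT_GAIN
from .episodes import AlertEpisode, GroundTruthEvent

__all__ = [
    "ConfusionMatrix",
    "PerformanceReport",
    "TwoByTwoResult",
    "TimeToAlertSummary",
    "build_confusion_matrix",
    "compute_metrics",
    "per_criterion_metrics",
    "two_by_two_test",
    "time_to_first_alert",
    "patient_outcomes",
]

CRITERION_FAMILIES = (WEIGHT_GAIN, LOSS_OF_OXYGEN, INCREASED_HEART_RATE)


@dataclass(frozen=True, slots=True)
class ConfusionMatrix:
    """Patient-level 2x2 table: alert status vs true AHF status."""

    tp: int  # alerted and true AHF
    fp: int  # alerted, no AHF
    fn: int  # no alert despite true AHF
    tn: int  # no alert, no AHF

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


@dataclass(frozen=True)
class PerformanceReport:
    """Confusion matrix plus the four derived diagnostic ratios.

    Ratios are proportions in [0, 1]; ``None`` marks an undefined ratio.
    ``per_criterion`` optionally maps each criterion family to its own
    metric dictionary.
    """

    matrix: ConfusionMatrix
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    per_criterion: dict[str, dict[str, float | None]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        m = self.matrix
        return {
            "matrix": {"tp": m.tp, "fp": m.fp, "fn": m.fn, "tn": m.tn},
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "per_criterion": self.per_criterion,
        }


def build_confusion_matrix(
    patient_labels: Mapping[str, tuple[bool, bool]] | pd.DataFrame,
) -> ConfusionMatrix:
    """Count patients into the 2x2 table.

    ``patient_labels`` maps patient id to ``(alerted, true_AHF)`` booleans,
    or is a DataFrame with boolean columns ``alerted`` and ``true_ahf``.
    """
    if isinstance(patient_labels, pd.DataFrame):
        pairs = list(zip(patient_labels["alerted"], patient_labels["true_ahf"]))
    else:
        pairs = list(patient_labels.values())
    tp = sum(1 for a, t in pairs if a and t)
    fp = sum(1 for a, t in pairs if a and not t)
    fn = sum(1 for a, t in pairs if not a and t)
    tn = sum(1 for a, t in pairs if not a and not t)
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def compute_metrics(matrix: ConfusionMatrix) -> PerformanceReport:
    """Sensitivity, specificity, PPV and NPV from a confusion matrix."""
    return PerformanceReport(
        matrix=matrix,
        sensitivity=_ratio(matrix.tp, matrix.tp + matrix.fn),
        specificity=_ratio(matrix.tn, matrix.tn + matrix.fp),
        ppv=_ratio(matrix.tp, matrix.tp + matrix.fp),
        npv=_ratio(matrix.tn, matrix.tn + matrix.fn),
    )


def patient_outcomes(
    patient_ids: Iterable[str],
    episodes: Sequence[AlertEpisode],
    truth: Sequence[GroundTruthEvent],
) -> pd.DataFrame:
    """Per-patient outcome table combining alerts and ground truth.

    Columns: ``alerted`` (any episode), ``true_ahf`` (any AHF event in
    truth), ``confirmed`` (any confirmed episode), ``first_alert_day``
    (days since enrollment of the earliest episode; the earliest *confirmed*
    episode for confirmed patients, since that episode determines the
    patient's label), ``criteria`` ("+"-joined union over the episodes that
    carry the patient's label), ``cause`` (cause of the earliest episode for
    purely-unconfirmed patients).
    """
    eps_by_patient: dict[str, list[AlertEpisode]] = {}
    for e in episodes:
        eps_by_patient.setdefault(e.patient_id, []).append(e)
    ahf_patients = {ev.patient_id for ev in truth if ev.event_type == "AHF"}

    rows = []
    for pid in patient_ids:
        eps = sorted(eps_by_patient.get(pid, []), key=lambda e: e.onset)
        confirmed_eps = [e for e in eps if e.label == "confirmed_AHF"]
        confirmed = bool(confirmed_eps)
        label_eps = confirmed_eps if confirmed else eps
        first = label_eps[0] if label_eps else None
        criteria: frozenset[str] = frozenset()
        for e in label_eps:
            criteria = criteria | e.criteria_types
        rows.append(
            {
                "patient_id": pid,
                "alerted": bool(eps),
                "true_ahf": pid in ahf_patients,
                "confirmed": confirmed,
                "first_alert_day": (
                    first.days_since_enrollment if first is not None else np.nan
                ),
                "criteria": "+".join(sorted(criteria)),
                "cause": (
                    eps[0].unconfirmed_cause if eps and not confirmed else None
                ),
            }
        )
    return pd.DataFrame(rows).set_index("patient_id")


def per_criterion_metrics(
    episodes: Sequence[AlertEpisode],
    cohort: pd.DataFrame,
    convention: str = "patient",
) -> dict[str, dict[str, float | None]]:
    """Per-family diagnostic metrics under a documented patient-level
    convention.

    For each family *f*: tp = confirmed-AHF patients whose confirming
    episode(s) include *f*; fn = confirmed-AHF patients whose confirming
    episodes lack *f*; fp = non-AHF patients with any episode including
    *f*; tn = the remaining non-AHF patients.  ``cohort`` is the
    :func:`patient_outcomes` table.

    Only the ``"patient"`` convention is implemented; how the original
    audit derived its per-criterion cells is not documented anywhere and
    cannot be reverse-engineered from the published counts.
    """
    if convention != "patient":
        raise ValueError(f"unknown per-criterion convention {convention!r}")

    eps_by_patient: dict[str, list[AlertEpisode]] = {}
    for e in episodes:
        eps_by_patient.setdefault(e.patient_id, []).append(e)

    out: dict[str, dict[str, float | None]] = {}
    confirmed = cohort[cohort["confirmed"]]
    non_ahf = cohort[~cohort["true_ahf"]]
    for fam in CRITERION_FAMILIES:
        tp = int(confirmed["criteria"].str.contains(fam).sum())
        fn = len(confirmed) - tp
        fp = 0
        for pid in non_ahf.index:
            if any(fam in e.criteria_types for e in eps_by_patient.get(pid, [])):
                fp += 1
        tn = len(non_ahf) - fp
        rep = compute_metrics(ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn))
        out[fam] = {
            "tp": tp,
            "fp": fp,
            "fn": fn,
            "tn": tn,
            "sensitivity": rep.sensitivity,
            "specificity": rep.specificity,
            "ppv": rep.ppv,
            "npv": rep.npv,
        }
    return out


@dataclass(frozen=True, slots=True)
class TwoByTwoResult:
    statistic: float
    p_value: float
    method: str  # "chi2_continuity" or "fisher_exact"


def two_by_two_test(a: int, b: int, c: int, d: int) -> TwoByTwoResult:
    """Association test on a 2x2 contingency table ``[[a, b], [c, d]]``.

    Uses the chi-square test with continuity correction; falls back to
    Fisher's exact test whenever any expected cell count is below 5, the
    standard small-sample rule.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    table = np.array([[a, b], [c, d]], dtype=float)
    if table.sum() == 0:
        raise ValueError("all-zero 2x2 table")
    expected = stats.contingency.expected_freq(table)
    if (expected < 5).any():
        res = stats.fisher_exact(table)
        return TwoByTwoResult(float(res.statistic), float(res.pvalue), "fisher_exact")
    chi2 = stats.chi2_contingency(table, correction=True)
    return TwoByTwoResult(float(chi2.statistic), float(chi2.pvalue), "chi2_continuity")


@dataclass(frozen=True, slots=True)
class TimeToAlertSummary:
    n: int
    median: float
    iqr_low: float
    iqr_high: float


def _order_stats(days: Sequence[float]) -> TimeToAlertSummary | None:
    if not days:
        return None
    q1, med, q3 = np.percentile(np.asarray(days, dtype=float), [25, 50, 75])
    return TimeToAlertSummary(len(days), float(med), float(q1), float(q3))


def time_to_first_alert(
    cohort: pd.DataFrame,
) -> dict[str, TimeToAlertSummary | None]:
    """Median and IQR of days from enrollment to first alert.

    Computed over alerted patients from the :func:`patient_outcomes` table,
    overall and split by patient label (for confirmed patients the clock
    stops at the episode that confirmed them).  Returns ``None`` entries
    when a group is empty.
    """
    alerted = cohort[cohort["alerted"]]
    return {
        "overall": _order_stats(list(alerted["first_alert_day"].dropna())),
        "confirmed_AHF": _order_stats(
            list(alerted.loc[alerted["confirmed"], "first_alert_day"].dropna())
        ),
        "unconfirmed": _order_stats(
            list(alerted.loc[~alerted["confirmed"], "first_alert_day"].dropna())
        ),
    }
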