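import datetime as dt

import pytest

from hfalert.cohort import DailyVitals, PatientRecord

START = dt.date(2020, 3, 1)


def make_record(
    weights=None,
    spo2=None,
    hr=None,
    *,
    patient_id="P001",
    start=START,
    n_days=None,
):
    """Build a PatientRecord from parallel per-day value lists.

    Lists may contain None for missing values; shorter lists are padded
    with None.  ``n_days`` defaults to the longest list.
    """
    seqs = [weights or [], spo2 or [], hr or []]
    n = n_days if n_days is not None else max(map(len, seqs))

    def get(seq, i):
        return seq[i] if i < len(seq) else None

    vitals = tuple(
        DailyVitals(
            patient_id,
            start + dt.timedelta(days=i),
            weight=get(seqs[0], i),
            spo2=get(seqs[1], i),
            heart_rate=get(seqs[2], i),
        )
        for i in range(n)
    )
    return PatientRecord(
        patient_id=patient_id,
        enrollment_day=start,
        followup_end=start + dt.timedelta(days=n - 1),
        vitals=vitals,
    )


@pytest.fixture
def record_factory():
    return make_record
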