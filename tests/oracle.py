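"""Brute-force re-statement of the clinical alert rule, independent of the
engine implementation.

Written directly from the rule's clinical wording with the default
thresholds hard-coded, no shared helpers with :mod:`hfalert.engine`.  Used
as the reference in equivalence tests.
"""

import datetime as dt


def brute_force_scan(record):
    """Return [(day, fired, path, criteria_types), ...] for every observed
    day, re-deriving every clause from scratch."""
    values = {}
    for v in record.vitals:
        values[v.day] = (v.weight, v.spo2, v.heart_rate)

    baseline = None
    for v in record.vitals:
        if v.weight is not None:
            baseline = v.weight
            break

    out = []
    for v in record.vitals:
        day = v.day
        weight, spo2, hr = values[day]

        # every pairwise weight gain over the last 4 days
        gains = []
        if weight is not None:
            for back in (1, 2, 3, 4):
                prior = values.get(day - dt.timedelta(days=back))
                if prior is not None and prior[0] is not None:
                    gains.append(weight - prior[0])
        window_gain = max(gains) if gains else None

        # major path: one severe abnormality suffices
        major = set()
        if hr is not None and hr > 110:
            major.add("increased_heart_rate")
        if spo2 is not None and spo2 < 90:
            major.add("loss_of_oxygen")
        if weight is not None and baseline is not None and weight - baseline >= 4:
            major.add("weight_gain")
        if window_gain is not None and window_gain >= 4:
            major.add("weight_gain")
        if major:
            out.append((day, True, "major", frozenset(major)))
            continue

        # minor path: two concurrent milder abnormalities
        minor = set()
        if hr is not None and hr > 90:
            minor.add("increased_heart_rate")
        if spo2 is not None and spo2 < 92:
            minor.add("loss_of_oxygen")
        if window_gain is not None and window_gain >= 2:
            minor.add("weight_gain")
        if len(minor) >= 2:
            out.append((day, True, "minor", frozenset(minor)))
        else:
            out.append((day, False, "none", frozenset()))
    return out
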