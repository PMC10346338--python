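import datetime

import numpy as np
import pandas as pd
import pytest

from pulserel.io import make_stream


def stream_from_rows(rows, provenance="test"):
    """Build a SampleStream from compact tuples.

    Each row: (participant_id, metric, iso_timestamp, value[, activity[, state]]).
    """
    recs = []
    for row in rows:
        pid, metric, ts, value = row[:4]
        activity = row[4] if len(row) > 4 else "unlabeled"
        state = row[5] if len(row) > 5 else "unlabeled"
        t = pd.Timestamp(ts)
        if t.tzinfo is None:
            raise ValueError("test rows must carry a UTC offset")
        offs = int(t.utcoffset().total_seconds() // 60)
        recs.append(
            {
                "participant_id": pid,
                "device_id": "dev",
                "timestamp": t.tz_convert("UTC"),
                "offset_min": offs,
                "metric": metric,
                "value": float(value),
                "activity": activity,
                "state": state,
            }
        )
    return make_stream(pd.DataFrame(recs), provenance=provenance)


def series_stream(pid, metric, values, start="2023-03-06T12:00:00-07:00", step_min=5, **kw):
    """A single participant's evenly spaced series."""
    t0 = pd.Timestamp(start)
    rows = [
        (pid, metric, (t0 + pd.Timedelta(minutes=step_min * i)).isoformat(), v)
        for i, v in enumerate(values)
    ]
    return stream_from_rows(rows, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(20230306)


@pytest.fixture
def small_stream():
    return stream_from_rows(
        [
            ("A", "bpm", "2023-03-06T10:00:00-07:00", 60, "rest"),
            ("A", "bpm", "2023-03-06T10:05:00-07:00", 62, "rest"),
            ("A", "bpm", "2023-03-06T10:10:00-07:00", 80, "walk"),
            ("B", "bpm", "2023-03-06T10:00:00-07:00", 55, "rest"),
        ]
    )


def night_times(day: datetime.date, start_h=23, end_h=7, step_min=5):
    """5-min grid local times from day start_h to next-day end_h inclusive."""
    t0 = pd.Timestamp(day) + pd.Timedelta(hours=start_h)
    t1 = pd.Timestamp(day) + pd.Timedelta(days=1, hours=end_h)
    return pd.date_range(t0, t1, freq=f"{step_min}min")
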