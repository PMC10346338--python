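"""Sleep-period detection from BPM sampling density, plus study exclusions.

Wearable PPG sensors only record successfully when the wearer is still, so a
long run of densely spaced heart-rate samples is a strong sleep signature.
A sleep period is the longest run, per participant per study day, of
consecutive BPM samples whose inter-sample gaps never exceed ``max_gap`` and
whose first-to-last span is at least ``min_duration``.  Study days run
noon-to-noon in local time so an overnight period crossing midnight belongs
to a single day.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass

import pandas as pd

from .io import SampleStream, local_wall_clock

MIN_DURATION = pd.Timedelta(hours=2)
MAX_GAP = pd.Timedelta(minutes=15)


@dataclass(frozen=True)
class SleepInterval:
    participant_id: str
    study_day: datetime.date
    start: pd.Timestamp  # UTC
    end: pd.Timestamp  # UTC
    n_samples: int

    @property
    def span(self) -> pd.Timedelta:
        return self.end - self.start


@dataclass
class Exclusion:
    rule: str
    participant_id: str
    study_day: datetime.date | None
    n_removed: int


def assign_study_day(stream: SampleStream) -> pd.Series:
    """Noon-to-noon local study day of every record (a date label)."""
    local = local_wall_clock(stream.records)
    return (local - pd.Timedelta(hours=12)).dt.date


def detect_sleep_periods(
    stream: SampleStream,
    min_duration: pd.Timedelta = MIN_DURATION,
    max_gap: pd.Timedelta = MAX_GAP,
) -> list[SleepInterval]:
    """Longest qualifying dense BPM run per participant per study day.

    Ties on span go to the earliest run.  Days with no qualifying run simply
    yield nothing; the empty list is a valid result.
    """
    df = stream.records
    bpm = df[df["metric"] == "bpm"]
    intervals: list[SleepInterval] = []
    for pid, grp in bpm.groupby("participant_id", sort=True):
        grp = grp.sort_values("timestamp", kind="mergesort")
        ts = grp["timestamp"].reset_index(drop=True)
        local = local_wall_clock(grp).reset_index(drop=True)
        if ts.empty:
            continue
        # maximal runs: break wherever the gap exceeds max_gap
        new_run = ts.diff() > max_gap
        run_id = new_run.cumsum()
        best: dict[datetime.date, SleepInterval] = {}
        for _, idx in ts.groupby(run_id).groups.items():
            start, end = ts.iloc[idx[0]], ts.iloc[idx[-1]]
            span = end - start
            if span < min_duration:
                continue
            day = (local.iloc[idx[0]] - pd.Timedelta(hours=12)).date()
            cand = SleepInterval(str(pid), day, start, end, n_samples=len(idx))
            prev = best.get(day)
            if prev is None or span > prev.span:  # tie keeps the earlier run
                best[day] = cand
        intervals.extend(best[d] for d in sorted(best))
    return intervals


def label_state(stream: SampleStream, intervals: list[SleepInterval]) -> SampleStream:
    """Mark records inside any interval as sleep, all others as wake.

    Interval membership is closed on both ends: the samples that define a run
    belong to it.
    """
    _check_no_overlap(intervals)
    df = stream.records.copy()
    df["state"] = "wake"
    for iv in intervals:
        mask = (
            (df["participant_id"] == iv.participant_id)
            & (df["timestamp"] >= iv.start)
            & (df["timestamp"] <= iv.end)
        )
        df.loc[mask, "state"] = "sleep"
    return stream.with_records(df)


def _check_no_overlap(intervals: list[SleepInterval]) -> None:
    by_pid: dict[str, list[SleepInterval]] = {}
    for iv in intervals:
        by_pid.setdefault(iv.participant_id, []).append(iv)
    for pid, ivs in by_pid.items():
        ivs = sorted(ivs, key=lambda i: i.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"overlapping sleep intervals for participant {pid}: "
                    f"[{a.start}, {a.end}] and [{b.start}, {b.end}]"
                )


def apply_study_exclusions(
    stream: SampleStream,
    intervals: list[SleepInterval],
    min_sleep_periods: int = 3,
    min_wake_hrv_per_day: int = 2,
) -> tuple[SampleStream, list[Exclusion]]:
    """Drop participants with too few sleep periods and sparse wake-HRV days.

    Participants with fewer than ``min_sleep_periods`` detected sleep periods
    are removed entirely.  Participant-days whose wakeful rMSSD count falls
    below ``min_wake_hrv_per_day`` lose those wake rMSSD records (a single
    wakeful HRV sample cannot support a within-day estimate).
    """
    df = stream.records.copy()
    report: list[Exclusion] = []

    periods_per_pid: dict[str, int] = {}
    for iv in intervals:
        periods_per_pid[iv.participant_id] = periods_per_pid.get(iv.participant_id, 0) + 1

    drop_pids = {
        pid
        for pid in df["participant_id"].unique()
        if periods_per_pid.get(pid, 0) < min_sleep_periods
    }
    for pid in sorted(drop_pids):
        n = int((df["participant_id"] == pid).sum())
        report.append(Exclusion("insufficient_sleep_periods", pid, None, n))
    df = df[~df["participant_id"].isin(drop_pids)]

    study_day = (local_wall_clock(df) - pd.Timedelta(hours=12)).dt.date
    wake_hrv = (df["metric"] == "rmssd") & (df["state"] == "wake")
    drop_mask = pd.Series(False, index=df.index)
    if wake_hrv.any():
        counts = df[wake_hrv].groupby(
            [df.loc[wake_hrv, "participant_id"], study_day[wake_hrv]]
        ).size()
        for (pid, day), n in counts.items():
            if n < min_wake_hrv_per_day:
                mask = wake_hrv & (df["participant_id"] == pid) & (study_day == day)
                drop_mask |= mask
                report.append(Exclusion("sparse_wake_hrv_day", pid, day, int(n)))
    df = df[~drop_mask]
    return stream.with_records(df), report


def intervals_frame(intervals: list[SleepInterval]) -> pd.DataFrame:
    """Intervals as a BED-like tidy table."""
    return pd.DataFrame(
        [
            (iv.participant_id, str(iv.study_day), iv.start.isoformat(), iv.end.isoformat(), iv.n_samples)
            for iv in intervals
        ],
        columns=["participant_id", "study_day", "start", "end", "n_samples"],
    )
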