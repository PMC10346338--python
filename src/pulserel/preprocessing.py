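"""Artifact filtering and aggregation to per-participant condition means.

Cleaning follows the two-step screening used for wearable PPG outputs: all
zero-valued samples are removed first (the vendor emits 0 for failed HRV
reads), then values more than ``n_sd`` standard deviations from each
participant's mean over their whole retained series.  Order matters and is
part of the contract: outlier statistics are computed on the zero-free
series, and the outlier filter is applied exactly once, never iterated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FilterLogEntry, SampleStream

CONDITION_KEYS = ("activity", "device", "state", "day")


@dataclass
class ConditionMeansTable:
    """Participant x condition grid of mean values and sample counts.

    ``means`` has NaN exactly where ``counts`` is zero.
    """

    means: pd.DataFrame  # index: participant_id, columns: condition labels
    counts: pd.DataFrame
    condition_key: str = ""
    metric: str = ""

    @property
    def participants(self) -> list:
        return list(self.means.index)

    @property
    def conditions(self) -> list:
        return list(self.means.columns)

    def to_replicates(self) -> dict[str, np.ndarray]:
        """Per-participant arrays of non-missing cell means (ICC input)."""
        return {
            pid: row.dropna().to_numpy(dtype=float) for pid, row in self.means.iterrows()
        }


def remove_zero_samples(stream: SampleStream) -> SampleStream:
    """Drop every record with value == 0, logging the removed fraction per metric."""
    df = stream.records
    log = []
    for metric, grp in df.groupby("metric", sort=True):
        n = len(grp)
        removed = int((grp["value"] == 0).sum())
        log.append(FilterLogEntry("zero_filter", str(metric), removed, removed / n if n else 0.0))
        if n and removed == n:
            warnings.warn(
                f"zero filter removed every '{metric}' sample; metric sub-stream is empty",
                stacklevel=2,
            )
    kept = df[df["value"] != 0]
    return stream.with_records(kept, extra_log=log)


def remove_outlier_samples(stream: SampleStream, n_sd: float = 2.0) -> SampleStream:
    """Drop records more than ``n_sd`` sample SDs from the participant mean.

    Mean and SD are computed once per (participant, metric) over the whole
    observation period (strict inequality; sample SD with divisor n-1).
    Series with fewer than 3 samples are left untouched because their SD is
    unstable.
    """
    if n_sd <= 0:
        raise ValueError("n_sd must be positive")
    df = stream.records
    drop = pd.Series(False, index=df.index)
    for (pid, metric), grp in df.groupby(["participant_id", "metric"], sort=False):
        if len(grp) < 3:
            warnings.warn(
                f"participant {pid} metric {metric}: only {len(grp)} samples; "
                "outlier filter skipped (SD unstable)",
                stacklevel=2,
            )
            continue
        mean = grp["value"].mean()
        sd = grp["value"].std(ddof=1)
        if sd == 0:
            continue
        drop.loc[grp.index] = (grp["value"] - mean).abs() > n_sd * sd
    log = []
    for metric, grp in df.groupby("metric", sort=True):
        n = len(grp)
        removed = int(drop.loc[grp.index].sum())
        log.append(
            FilterLogEntry(f"outlier_filter_{n_sd:g}sd", str(metric), removed, removed / n if n else 0.0)
        )
    return stream.with_records(df[~drop], extra_log=log)


def _condition_column(stream: SampleStream, condition_key: str) -> pd.Series:
    if condition_key == "device":
        return stream.records["device_id"]
    if condition_key == "day":
        from .segmentation import assign_study_day

        return assign_study_day(stream).astype(str)
    if condition_key in ("activity", "state"):
        return stream.records[condition_key]
    raise ValueError(f"condition_key must be one of {CONDITION_KEYS}, got '{condition_key}'")


def condition_means(
    stream: SampleStream, condition_key: str, metric: str | None = None
) -> ConditionMeansTable:
    """Mean value per (participant, condition) cell for one metric.

    ``condition_key`` selects the grouping: activity label, device, sleep/wake
    state, or study day (noon-to-noon).  The stream must contain a single
    metric unless ``metric`` selects one.
    """
    df = stream.records
    cond = _condition_column(stream, condition_key)
    if metric is not None:
        keep = df["metric"] == metric
        df, cond = df[keep], cond[keep]
    else:
        present = df["metric"].unique()
        if len(present) > 1:
            raise ValueError(
                f"stream holds metrics {sorted(present)}; pass metric= to choose one"
            )
        metric = present[0] if len(present) else ""
    if condition_key in ("activity", "state"):
        unlabeled = cond == "unlabeled"
        if unlabeled.any():
            i = df.index[unlabeled][0]
            raise ValueError(
                f"condition_key '{condition_key}' is unlabeled on record {i} "
                f"(participant {df.at[i, 'participant_id']})"
            )
    work = pd.DataFrame(
        {"participant_id": df["participant_id"], "condition": cond, "value": df["value"]}
    )
    counts = (
        work.pivot_table(
            index="participant_id", columns="condition", values="value", aggfunc="count"
        )
        .fillna(0)
        .astype(int)
    )
    means = work.pivot_table(
        index="participant_id", columns="condition", values="value", aggfunc="mean"
    )
    means = means.reindex(index=counts.index, columns=counts.columns)
    return ConditionMeansTable(
        means=means, counts=counts, condition_key=condition_key, metric=str(metric)
    )


def filter_log_frame(stream: SampleStream) -> pd.DataFrame:
    """The stream's filter log as a tidy DataFrame (rule, metric, removed, fraction)."""
    return pd.DataFrame(
        [(e.rule, e.metric, e.removed, e.fraction) for e in stream.filter_log],
        columns=["rule", "metric", "removed", "fraction"],
    )
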