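"""Shared data model and CSV I/O for biometric sample streams and EMA prompts.

Every analysis module consumes :class:`SampleStream`, a thin wrapper around a
pandas DataFrame with a fixed, validated column layout.  Timestamps must carry
an explicit UTC offset: sleep-window logic downstream depends on local clock
time, so naive timestamps are rejected at the door.  Internally each instant
is stored as a UTC timestamp plus its original offset in minutes, which makes
ordering cheap and local wall-clock time recoverable exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

METRICS = ("bpm", "rmssd")
STATES = ("sleep", "wake", "unlabeled")
UNLABELED = "unlabeled"

#: canonical column order of SampleStream.records
SAMPLE_COLUMNS = (
    "participant_id",
    "device_id",
    "timestamp",
    "offset_min",
    "metric",
    "value",
    "activity",
    "state",
)

EMA_ITEMS = (
    "happy",
    "energetic",
    "nervous",
    "afraid",
    "irritable",
    "angry",
    "pain",
    "discomfort",
)

_OFFSET_RE = re.compile(r"(?:Z|[+-]\d{2}:?\d{2})$")


class SchemaError(ValueError):
    """A declared column is missing or an unknown category was supplied."""


class RowError(ValueError):
    """A row failed to parse; the message carries 1-based data row numbers."""


@dataclass
class FilterLogEntry:
    rule: str
    metric: str
    removed: int
    fraction: float


@dataclass
class SampleStream:
    """Ordered biometric records plus provenance and filtering history.

    ``records`` is sorted by (participant_id, metric, timestamp); the
    ``filter_log`` accumulates one entry per (cleaning rule, metric) so data
    loss is always visible downstream.
    """

    records: pd.DataFrame
    provenance: str = ""
    filter_log: list[FilterLogEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def local_time(self) -> pd.Series:
        """Local wall-clock time (naive) of every record."""
        return local_wall_clock(self.records)

    def with_records(self, records: pd.DataFrame, *, extra_log=()) -> "SampleStream":
        return SampleStream(
            records=records.reset_index(drop=True),
            provenance=self.provenance,
            filter_log=list(self.filter_log) + list(extra_log),
        )

    def copy(self) -> "SampleStream":
        return replace(self, records=self.records.copy(), filter_log=list(self.filter_log))


@dataclass
class ValidationIssue:
    rule: str
    message: str


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.issues

    def __str__(self) -> str:
        if self.valid:
            return "valid stream (no issues)"
        return "\n".join(f"[{i.rule}] {i.message}" for i in self.issues)


def local_wall_clock(records: pd.DataFrame) -> pd.Series:
    """Naive local wall-clock time from UTC timestamps and per-row offsets."""
    utc_naive = records["timestamp"].dt.tz_localize(None)
    return utc_naive + pd.to_timedelta(records["offset_min"], unit="m")


def _parse_timestamps(raw: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Parse ISO 8601 strings with mandatory offsets.

    Returns (utc timestamps, offset minutes).  Raises RowError naming the
    offending 1-based data rows for naive or unparseable entries.
    """
    raw = raw.astype(str).str.strip()
    has_offset = raw.str.contains(_OFFSET_RE)
    if not has_offset.all():
        bad = (raw.index[~has_offset] + 1).tolist()[:10]
        raise RowError(
            f"timestamps without an explicit UTC offset at data row(s) {bad}; "
            "naive timestamps are rejected because sleep-window logic needs "
            "local clock time"
        )
    try:
        aware = pd.to_datetime(raw, format="ISO8601", utc=False)
    except (ValueError, pd.errors.ParserError) as exc:
        raise RowError(f"unparseable ISO 8601 timestamp: {exc}") from exc
    # `aware` may be tz-aware datetime64 (uniform offset) or object (mixed)
    if isinstance(aware.dtype, pd.DatetimeTZDtype):
        offs = aware.apply(lambda t: int(t.utcoffset().total_seconds() // 60))
        utc = aware.dt.tz_convert("UTC")
    else:
        offs = aware.apply(lambda t: int(t.utcoffset().total_seconds() // 60))
        utc = pd.to_datetime(raw, format="ISO8601", utc=True)
    return utc, offs.astype("int64")


def _sort_records(records: pd.DataFrame) -> pd.DataFrame:
    return records.sort_values(
        ["participant_id", "metric", "timestamp", "device_id"], kind="mergesort"
    ).reset_index(drop=True)


def make_stream(records: pd.DataFrame, provenance: str = "") -> SampleStream:
    """Build a SampleStream from a DataFrame already holding typed columns."""
    df = records.copy()
    for col, default in (("activity", UNLABELED), ("state", UNLABELED)):
        if col not in df.columns:
            df[col] = default
        df[col] = df[col].fillna(default).replace("", default).astype(str)
    if "offset_min" not in df.columns:
        raise SchemaError("records need an offset_min column (UTC offset in minutes)")
    df["value"] = df["value"].astype(float)
    df["offset_min"] = df["offset_min"].astype("int64")
    df = df[list(SAMPLE_COLUMNS)]
    return SampleStream(records=_sort_records(df), provenance=provenance)


def read_samples(path, schema: dict | None = None, provenance: str | None = None) -> SampleStream:
    """Read a samples CSV into a validated, sorted :class:`SampleStream`.

    ``schema`` maps file column names to canonical field names
    (participant_id, device_id, timestamp, metric, value, activity, state)
    when the file uses different headers.
    """
    raw = pd.read_csv(path, dtype=str)
    if schema:
        missing = [c for c in schema if c not in raw.columns]
        if missing:
            raise SchemaError(f"schema names absent column(s) {missing} in {path}")
        raw = raw.rename(columns=schema)
    required = ["participant_id", "device_id", "timestamp", "metric", "value"]
    for col in required:
        if col not in raw.columns:
            raise SchemaError(f"missing required column '{col}' in {path}")
    raw = raw.reset_index(drop=True)

    metric = raw["metric"].astype(str).str.strip().str.lower()
    unknown = ~metric.isin(METRICS)
    if unknown.any():
        bad = sorted(metric[unknown].unique())
        raise SchemaError(
            f"unknown metric(s) {bad}; supported metrics are {list(METRICS)}"
        )

    value = pd.to_numeric(raw["value"], errors="coerce")
    bad_value = value.isna()
    if bad_value.any():
        rows = (raw.index[bad_value] + 1).tolist()[:10]
        raise RowError(f"non-numeric value at data row(s) {rows} in {path}")

    utc, offs = _parse_timestamps(raw["timestamp"])

    df = pd.DataFrame(
        {
            "participant_id": raw["participant_id"].astype(str),
            "device_id": raw["device_id"].astype(str),
            "timestamp": utc,
            "offset_min": offs,
            "metric": metric,
            "value": value.astype(float),
            "activity": raw.get("activity"),
            "state": raw.get("state"),
        }
    )
    return make_stream(df, provenance=provenance if provenance is not None else str(path))


def _format_timestamps(records: pd.DataFrame) -> pd.Series:
    local = local_wall_clock(records).dt.strftime("%Y-%m-%dT%H:%M:%S")
    offs = records["offset_min"].astype(int)
    sign = np.where(offs < 0, "-", "+")
    hours = (abs(offs) // 60).astype(int).map("{:02d}".format)
    mins = (abs(offs) % 60).astype(int).map("{:02d}".format)
    return local + pd.Series(sign, index=local.index) + hours + ":" + mins


def write_samples(stream: SampleStream, path) -> object:
    """Write the stream as the canonical samples CSV (ISO 8601 timestamps)."""
    out = stream.records.copy()
    ts = _format_timestamps(out) if len(out) else pd.Series([], dtype=str)
    out = pd.DataFrame(
        {
            "participant_id": out["participant_id"],
            "device_id": out["device_id"],
            "timestamp": ts,
            "metric": out["metric"],
            "value": out["value"],
            "activity": out["activity"],
            "state": out["state"],
        }
    )
    out.to_csv(path, index=False)
    return path


def validate_stream(stream: SampleStream) -> ValidationReport:
    """Check SampleStream invariants; reports violations, never raises."""
    report = ValidationReport()
    df = stream.records
    add = report.issues.append

    bad_metric = ~df["metric"].isin(METRICS)
    for i in df.index[bad_metric]:
        add(ValidationIssue("metric_enum", f"row {i}: unknown metric '{df.at[i, 'metric']}'"))
    nonfinite = ~np.isfinite(df["value"].to_numpy(dtype=float))
    for i in df.index[nonfinite]:
        add(ValidationIssue("finite_value", f"row {i}: non-finite value"))
    negative = df["value"] < 0
    for i in df.index[negative]:
        add(ValidationIssue("nonnegative_value", f"row {i}: negative value {df.at[i, 'value']}"))
    bad_state = ~df["state"].isin(STATES)
    for i in df.index[bad_state]:
        add(ValidationIssue("state_enum", f"row {i}: unknown state '{df.at[i, 'state']}'"))

    key = ["participant_id", "device_id", "metric", "timestamp"]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        for _, grp in df[dup].groupby(key, sort=False):
            pid, dev, met, ts = grp.iloc[0][key]
            add(
                ValidationIssue(
                    "unique_key",
                    f"duplicate (participant={pid}, device={dev}, metric={met}, "
                    f"timestamp={ts}) x{len(grp)}",
                )
            )

    sort_key = df[["participant_id", "metric", "timestamp"]]
    if not sort_key.equals(_sort_records(df)[["participant_id", "metric", "timestamp"]]):
        add(ValidationIssue("sorted", "records are not sorted by (participant, metric, timestamp)"))

    for entry in stream.filter_log:
        if not 0.0 <= entry.fraction <= 1.0:
            add(
                ValidationIssue(
                    "filter_log_fraction",
                    f"filter_log entry {entry.rule}/{entry.metric} has fraction "
                    f"{entry.fraction} outside [0, 1]",
                )
            )
    return report


# ---------------------------------------------------------------------------
# EMA prompts


def read_ema(path, provenance: str | None = None) -> pd.DataFrame:
    """Read an EMA prompt CSV: participant_id, timestamp, eight 1-10 items.

    Missing ratings are allowed (empty cells); present ratings must be
    integers in [1, 10].
    """
    raw = pd.read_csv(path, dtype=str)
    for col in ("participant_id", "timestamp"):
        if col not in raw.columns:
            raise SchemaError(f"missing required column '{col}' in {path}")
    missing_items = [c for c in EMA_ITEMS if c not in raw.columns]
    if missing_items:
        raise SchemaError(f"missing EMA item column(s) {missing_items} in {path}")
    raw = raw.reset_index(drop=True)
    utc, offs = _parse_timestamps(raw["timestamp"])
    out = pd.DataFrame(
        {"participant_id": raw["participant_id"].astype(str), "timestamp": utc, "offset_min": offs}
    )
    for item in EMA_ITEMS:
        vals = pd.to_numeric(raw[item], errors="coerce")
        given = raw[item].notna() & (raw[item].astype(str).str.strip() != "")
        bad = given & vals.isna()
        if bad.any():
            rows = (raw.index[bad] + 1).tolist()[:10]
            raise RowError(f"non-numeric rating '{item}' at data row(s) {rows}")
        ok = vals.dropna()
        out_of_range = ok[(ok < 1) | (ok > 10) | (ok != ok.round())]
        if len(out_of_range):
            rows = (out_of_range.index + 1).tolist()[:10]
            raise RowError(
                f"rating '{item}' must be an integer in [1, 10]; bad data row(s) {rows}"
            )
        out[item] = vals
    return out


def write_ema(ema: pd.DataFrame, path) -> object:
    out = pd.DataFrame(
        {
            "participant_id": ema["participant_id"],
            "timestamp": _format_timestamps(ema) if len(ema) else pd.Series([], dtype=str),
        }
    )
    for item in EMA_ITEMS:
        out[item] = ema[item].map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(path, index=False)
    return path
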