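"""End-to-end pipeline: clean -> segment -> between -> within (-> EMA).

`run_report` executes the full reliability analysis on a samples CSV and
writes tidy tables: a between-person table (label, ICC, CI, N), a
within-person table (label, mean beta, SD of beta across iterations), the
filter and exclusion logs, detected sleep intervals, optional EMA
associations, and a manifest recording configuration and seeds so that the
same config and seed always reproduce byte-identical tables.
"""

from __future__ import annotations

import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, between, ema, preprocessing, segmentation, within
from .io import SampleStream, read_ema, read_samples
from .lmm import DegenerateDesignError


@dataclass
class RunConfig:
    samples_path: str = ""
    ema_path: str | None = None
    out_dir: str = "pulserel_report"
    # filtering
    zero_filter: bool = True
    n_sd: float = 2.0
    # segmentation
    min_duration_h: float = 2.0
    max_gap_min: float = 15.0
    min_sleep_periods: int = 3
    min_wake_hrv_per_day: int = 2
    # split-half
    split_method: str = "both"  # time_sensitive | random | both
    n_iterations: int = 1000
    master_seed: int = 0
    unit_preset: str = "study2"
    random_factors: tuple[str, ...] = ("participant",)
    # ICC
    confidence: float = 0.95
    icc_form: str = "single"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.random_factors, list):
            cfg.random_factors = tuple(cfg.random_factors)
        return cfg

    def validate(self) -> None:
        if self.split_method not in ("time_sensitive", "random", "both"):
            raise ValueError(f"bad split_method '{self.split_method}'")
        if not 0 < self.confidence < 1:
            raise ValueError("confidence must be in (0, 1)")
        if self.n_sd <= 0 or self.n_iterations < 1 or self.min_sleep_periods < 0:
            raise ValueError("filter/split settings out of range")
        if self.unit_preset not in within.UNIT_PRESETS:
            raise ValueError(f"unknown unit preset '{self.unit_preset}'")
        for f in self.random_factors:
            if f not in ("participant", "situation"):
                raise ValueError(f"unknown random factor '{f}'")


@dataclass
class ReportBundle:
    out_dir: Path
    between_table: pd.DataFrame
    within_table: pd.DataFrame
    filter_log: pd.DataFrame
    exclusions: pd.DataFrame
    intervals: pd.DataFrame
    ema_table: pd.DataFrame | None = None
    files: list[str] = field(default_factory=list)


def _log(stage: str, msg: str) -> None:
    print(f"[pulserel:{stage}] {msg}", file=sys.stderr)


def _stage(name: str):
    class _ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            return False

    return _ctx()


def run_report(config: RunConfig, stream: SampleStream | None = None) -> ReportBundle:
    """Run the full pipeline and write the report bundle to config.out_dir."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    with _stage("read"):
        if stream is None:
            stream = read_samples(config.samples_path)
        _log("read", f"{len(stream)} records")

    with _stage("clean"):
        if config.zero_filter:
            stream = preprocessing.remove_zero_samples(stream)
        stream = preprocessing.remove_outlier_samples(stream, n_sd=config.n_sd)
        _log("clean", f"{len(stream)} records retained")

    with _stage("segment"):
        intervals = segmentation.detect_sleep_periods(
            stream,
            min_duration=pd.Timedelta(hours=config.min_duration_h),
            max_gap=pd.Timedelta(minutes=config.max_gap_min),
        )
        stream = segmentation.label_state(stream, intervals)
        stream, exclusions = segmentation.apply_study_exclusions(
            stream,
            intervals,
            min_sleep_periods=config.min_sleep_periods,
            min_wake_hrv_per_day=config.min_wake_hrv_per_day,
        )
        _log("segment", f"{len(intervals)} sleep intervals, {len(exclusions)} exclusions")

    metrics = sorted(stream.records["metric"].unique())
    kept_pids = set(stream.records["participant_id"].unique())
    kept_intervals = [iv for iv in intervals if iv.participant_id in kept_pids]

    with _stage("between"):
        rows = []
        for metric in metrics:
            for state in ("sleep", "wake"):
                sub = stream.with_records(stream.records[stream.records["state"] == state])
                try:
                    table = preprocessing.condition_means(sub, "day", metric=metric)
                    decomp = between.decompose_oneway(table)
                    fn = between.icc_single if config.icc_form == "single" else between.icc_average
                    res = fn(decomp, confidence=config.confidence)
                except (between.InsufficientDataError, between.UndefinedEstimateError) as exc:
                    _log("between", f"{metric}/{state}: skipped ({exc})")
                    continue
                rows.append(
                    (
                        f"{metric}_{state}",
                        res.estimate,
                        res.ci_low,
                        res.ci_high,
                        res.n,
                        between.classify_icc(max(-1.0, min(1.0, res.estimate))),
                        res.p_value,
                    )
                )
        between_table = pd.DataFrame(
            rows, columns=["label", "icc", "ci_low", "ci_high", "n", "classification", "p_value"]
        )

    with _stage("within"):
        rows = []
        for metric in metrics:
            for state in ("sleep", "wake"):
                sub = stream.with_records(stream.records[stream.records["state"] == state])
                label = f"{metric}_{state}"
                ts_beta = float("nan")
                if config.split_method in ("time_sensitive", "both"):
                    try:
                        pairs = within.split_time_sensitive(sub, config.unit_preset, metric=metric)
                        ts_fit = within.fit_split_model(pairs, config.random_factors)
                        ts_beta = ts_fit.beta
                    except DegenerateDesignError as exc:
                        _log("within", f"{label}: time-sensitive skipped ({exc})")
                mean_beta = sd_beta = float("nan")
                if config.split_method in ("random", "both"):
                    try:
                        summary = within.random_split_distribution(
                            sub,
                            config.unit_preset,
                            random_factors=config.random_factors,
                            n_iterations=config.n_iterations,
                            master_seed=config.master_seed,
                            metric=metric,
                        )
                        mean_beta, sd_beta = summary.mean_beta, summary.sd_beta
                    except (within.EstimationError, DegenerateDesignError) as exc:
                        _log("within", f"{label}: random split skipped ({exc})")
                rows.append((label, ts_beta, mean_beta, sd_beta))
        within_table = pd.DataFrame(
            rows, columns=["label", "time_sensitive_beta", "mean_beta", "sd_beta"]
        )

    ema_table = None
    if config.ema_path:
        with _stage("ema"):
            records = read_ema(config.ema_path)
            affect = ema.daily_affect(ema.score_prompts(records))
            bio = ema.daily_biometrics(stream)
            results = ema.fit_lagged_models(affect, bio)
            ema_table = ema.association_frame(results)

    with _stage("write"):
        files = []

        def save(df: pd.DataFrame, name: str, sep=","):
            path = out_dir / name
            df.to_csv(path, index=False, sep=sep, float_format="%.10g")
            files.append(str(path))

        save(between_table, "between_reliability.csv")
        save(within_table, "within_reliability.csv")
        save(preprocessing.filter_log_frame(stream), "filter_log.csv")
        excl_df = pd.DataFrame(
            [(e.rule, e.participant_id, str(e.study_day), e.n_removed) for e in exclusions],
            columns=["rule", "participant_id", "study_day", "n_removed"],
        )
        save(excl_df, "exclusions.csv")
        save(segmentation.intervals_frame(kept_intervals), "sleep_intervals.tsv", sep="\t")
        if ema_table is not None:
            save(ema_table, "ema_associations.csv")
        manifest = {
            "pulserel_version": __version__,
            "config": asdict(config),
            "n_records_final": int(len(stream)),
            "metrics": metrics,
        }
        manifest["config"]["random_factors"] = list(config.random_factors)
        mpath = out_dir / "manifest.yaml"
        with open(mpath, "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
        files.append(str(mpath))

    return ReportBundle(
        out_dir=out_dir,
        between_table=between_table,
        within_table=within_table,
        filter_log=preprocessing.filter_log_frame(stream),
        exclusions=excl_df,
        intervals=segmentation.intervals_frame(kept_intervals),
        ema_table=ema_table,
        files=files,
    )
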