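"""Within-person reliability via split-half aggregation and mixed-model slopes.

Each analysis unit (e.g. a participant x activity cell, or a participant x
study-day x state cell) contributes a pair of half-means: its samples are
numbered by acquisition order and either interleaved odd/even (the
time-sensitive split, pairing samples as close in time as possible) or
partitioned at random.  A random-intercept mixed model then predicts one
half from the other; the slope *beta* is the reliability estimate.  Random
splitting is repeated many times and summarised by the distribution of betas.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SampleStream
from .lmm import DegenerateDesignError, LmmFit, fit_lmm

#: unit presets: columns grouped together with participant_id
UNIT_PRESETS = {
    "study1": ("activity", "device_id"),  # lab protocol: activity x device cells
    "study2": ("study_day", "state"),  # ambulatory: day x sleep/wake cells
}


class EstimationError(RuntimeError):
    pass


@dataclass
class SplitPairTable:
    """Per-unit (predictor half, criterion half) aggregate pairs.

    The odd-position (or odd-sized) half is the criterion, the even half the
    predictor; direction is fixed by convention and documented.
    """

    table: pd.DataFrame  # participant_id, *unit_cols, predictor_mean, criterion_mean, n_odd, n_even
    unit_cols: tuple[str, ...]
    dropped: list[tuple] = field(default_factory=list)  # units with < 2 samples

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class SplitHalfFit:
    beta: float
    intercept: float
    se: float
    t_stat: float
    df: float
    p_value: float
    random_effects_spec: tuple[str, ...]
    converged: bool
    n_units: int
    fit: LmmFit | None = None


@dataclass
class BetaDistributionSummary:
    mean_beta: float
    sd_beta: float
    quantiles: dict[float, float]
    n_iterations: int
    n_failed: int
    master_seed: int
    betas: np.ndarray = field(default=None, repr=False)
    high_failure_warning: bool = False


def _resolve_units(stream: SampleStream, unit_key, metric: str | None):
    """Return (records restricted to one metric, unit column tuple)."""
    unit_cols = UNIT_PRESETS.get(unit_key, unit_key) if isinstance(unit_key, str) else tuple(unit_key)
    if isinstance(unit_cols, str):
        unit_cols = (unit_cols,)
    df = stream.records
    if metric is not None:
        df = df[df["metric"] == metric]
    else:
        present = df["metric"].unique()
        if len(present) > 1:
            raise ValueError(
                f"stream holds metrics {sorted(present)}; pass metric= to choose one"
            )
    df = df.copy()
    for col in unit_cols:
        if col == "study_day" and "study_day" not in df.columns:
            from .segmentation import assign_study_day

            sub = stream.with_records(df)
            df["study_day"] = assign_study_day(sub).astype(str)
        elif col == "device":
            unit_cols = tuple("device_id" if c == "device" else c for c in unit_cols)
        elif col not in df.columns:
            raise ValueError(f"unknown unit column '{col}'")
    return df, unit_cols


def _prepare_units(stream, unit_key, metric) -> tuple[list[tuple[tuple, np.ndarray]], tuple]:
    """Per-unit time-ordered value arrays, resolved once per stream."""
    df, unit_cols = _resolve_units(stream, unit_key, metric)
    keys = ["participant_id", *unit_cols]
    df = df.sort_values([*keys, "timestamp"], kind="mergesort")
    units = []
    for key, grp in df.groupby(keys, sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        units.append((key, grp["value"].to_numpy()))
    return units, unit_cols


def _pairs_from_units(units, assign_half) -> tuple[list, list]:
    rows, dropped = [], []
    for key, values in units:
        m = len(values)
        if m < 2:
            dropped.append(key)
            continue
        odd_mask = assign_half(m, key)
        odd, even = values[odd_mask], values[~odd_mask]
        rows.append((*key, even.mean(), odd.mean(), len(odd), len(even)))
    return rows, dropped


def _build_table(rows, dropped, unit_cols) -> SplitPairTable:
    cols = ["participant_id", *unit_cols, "predictor_mean", "criterion_mean", "n_odd", "n_even"]
    return SplitPairTable(
        table=pd.DataFrame(rows, columns=cols), unit_cols=tuple(unit_cols), dropped=dropped
    )


def split_time_sensitive(
    stream: SampleStream, unit_key, metric: str | None = None
) -> SplitPairTable:
    """Odd/even split by acquisition order within each unit.

    Samples are numbered 1..m in time order; odd positions form the criterion
    half (receiving the extra sample when m is odd) and even positions the
    predictor half.  Units with a single sample are dropped and reported.
    """
    units, unit_cols = _prepare_units(stream, unit_key, metric)

    def assign(m, _key):
        return np.arange(1, m + 1) % 2 == 1

    rows, dropped = _pairs_from_units(units, assign)
    return _build_table(rows, dropped, unit_cols)


def _unit_seed(master_seed: int, iteration: int, key: tuple) -> np.random.Generator:
    tag = zlib.crc32("|".join(map(str, key)).encode())
    ss = np.random.SeedSequence([int(master_seed) % 2**31, int(iteration), tag])
    return np.random.default_rng(ss)


def split_random(
    stream: SampleStream,
    unit_key,
    seed: int,
    metric: str | None = None,
    iteration: int = 0,
) -> SplitPairTable:
    """Uniformly random partition of each unit into halves of sizes
    ceil(m/2) and floor(m/2); fully determined by (seed, unit, iteration)."""
    units, unit_cols = _prepare_units(stream, unit_key, metric)
    rows, dropped = _pairs_from_units(units, _random_assigner(seed, iteration))
    return _build_table(rows, dropped, unit_cols)


def _random_assigner(seed: int, iteration: int):
    def assign(m, key):
        rng = _unit_seed(seed, iteration, key)
        idx = rng.permutation(m)
        mask = np.zeros(m, dtype=bool)
        mask[idx[: (m + 1) // 2]] = True  # criterion half gets the extra sample
        return mask

    return assign


def _random_factor_labels(pairs: SplitPairTable, factor: str) -> np.ndarray:
    t = pairs.table
    if factor == "participant":
        return t["participant_id"].to_numpy()
    if factor == "situation":
        cols = [c for c in pairs.unit_cols]
        if not cols:
            raise ValueError("no unit columns available for a 'situation' random factor")
        return t[cols].astype(str).agg("|".join, axis=1).to_numpy()
    raise ValueError(f"random factor must be 'participant' or 'situation', got '{factor}'")


def fit_split_model(
    pairs: SplitPairTable,
    random_factors: tuple[str, ...] = ("participant",),
    compute_df: bool = True,
) -> SplitHalfFit:
    """Mixed model criterion ~ intercept + beta * predictor + (1 | factor)...

    The t test of beta uses Satterthwaite degrees of freedom.
    """
    t = pairs.table
    if len(t) < 3:
        raise DegenerateDesignError(f"need >= 3 split pairs, have {len(t)}")
    x = t["predictor_mean"].to_numpy(dtype=float)
    y = t["criterion_mean"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateDesignError("predictor half is constant across all units")
    X = np.column_stack([np.ones_like(x), x])
    groups = {f: _random_factor_labels(pairs, f) for f in random_factors}
    fit = fit_lmm(y, X, groups=groups, names=("intercept", "predictor"), compute_df=compute_df)
    j = fit.names.index("predictor")
    return SplitHalfFit(
        beta=float(fit.beta[j]),
        intercept=float(fit.beta[0]),
        se=float(fit.se[j]),
        t_stat=float(fit.t_stat[j]),
        df=float(fit.df[j]),
        p_value=float(fit.p_value[j]),
        random_effects_spec=tuple(random_factors),
        converged=fit.converged,
        n_units=len(t),
        fit=fit,
    )


def random_split_distribution(
    stream: SampleStream,
    unit_key,
    random_factors: tuple[str, ...] = ("participant",),
    n_iterations: int = 1000,
    master_seed: int = 0,
    metric: str | None = None,
    quantile_probs: tuple[float, ...] = (0.025, 0.25, 0.5, 0.75, 0.975),
) -> BetaDistributionSummary:
    """Repeat the random split ``n_iterations`` times and summarise the betas.

    The mean beta over converged fits is the within-person reliability
    estimate; failed fits are counted, and a >10% failure rate raises a
    prominent warning on the summary.
    """
    units, unit_cols = _prepare_units(stream, unit_key, metric)
    betas = []
    n_failed = 0
    for it in range(n_iterations):
        rows, dropped = _pairs_from_units(units, _random_assigner(master_seed, it))
        pairs = _build_table(rows, dropped, unit_cols)
        try:
            fit = fit_split_model(pairs, random_factors, compute_df=False)
        except DegenerateDesignError:
            n_failed += 1
            continue
        if fit.converged and np.isfinite(fit.beta):
            betas.append(fit.beta)
        else:
            n_failed += 1
    if not betas:
        raise EstimationError("every random-split iteration failed to converge")
    betas = np.asarray(betas)
    high_failure = n_failed > 0.1 * n_iterations
    if high_failure:
        warnings.warn(
            f"{n_failed}/{n_iterations} random-split fits failed; "
            "summary may be unrepresentative",
            stacklevel=2,
        )
    return BetaDistributionSummary(
        mean_beta=float(betas.mean()),
        sd_beta=float(betas.std(ddof=1)) if len(betas) > 1 else 0.0,
        quantiles={p: float(np.quantile(betas, p)) for p in quantile_probs},
        n_iterations=n_iterations,
        n_failed=n_failed,
        master_seed=master_seed,
        betas=betas,
        high_failure_warning=high_failure,
    )
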