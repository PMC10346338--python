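"""Ground-truth simulators for the variance-components measurement model.

A biometric sample is modelled as x = mu + r_i + s_j + v, with independent
Gaussian participant effects r_i ~ N(0, sigma_r^2), situation effects
s_j ~ N(0, sigma_s^2), and residual noise v ~ N(0, sigma_v^2).  The implied
population between-person reliability is rho = sigma_r^2 / (sigma_r^2 +
sigma_s^2 + sigma_v^2) for raw samples (sigma_s = 0 recovers the classic
two-component form).

Two generators realise this model: a matrix-form generator (participants x
situations x replicates, no timestamps) for estimator checks, and a
timestamped stream generator that reproduces the sampling regime of a
wrist-worn PPG sensor: a 5-minute grid, dense sampling inside a nightly
sleep window, sparse (thinned) wakeful sampling, zero-valued artifact
samples, and occasional spikes.  Artifacts are injected after the noise-free
truth is stored, so filters can be scored for exact recall.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import SampleStream, make_stream

_DEFAULT_START = datetime.date(2023, 3, 6)
_DEFAULT_OFFSET_MIN = -420  # UTC-7, a fixed local offset (no DST within a study week)


@dataclass
class SimulationConfig:
    """Parameters of the variance-components model and the sampling schedule.

    Units: mu and the sigmas are in the metric's units (beats/min or ms);
    the sampling period is in minutes; the sleep window is a daily
    local-time interval; retention/rates are probabilities.
    """

    mu: float = 70.0
    sigma_r: float = 8.0  # SD of participant effects
    sigma_s: float = 3.0  # SD of situation effects
    sigma_v: float = 2.0  # SD of residual noise (sleep noise for streams)
    sigma_v_wake: float | None = None  # wakeful residual SD; defaults to sigma_v
    n_participants: int = 10
    n_situations: int = 4
    k_replicates: int = 4
    sampling_period_min: int = 5
    sleep_window: tuple[datetime.time, datetime.time] = (
        datetime.time(23, 0),
        datetime.time(7, 0),
    )
    wake_retention: float = 0.10
    zero_rate: float = 0.0
    outlier_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("sigma_r", "sigma_s", "sigma_v"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("wake_retention", "zero_rate", "outlier_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        for name in ("n_participants", "n_situations", "k_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def wake_sigma(self) -> float:
        return self.sigma_v if self.sigma_v_wake is None else self.sigma_v_wake

    def population_icc(self, include_situation: bool = True) -> float:
        """Population rho implied by the variance components (raw samples)."""
        denom = self.sigma_r**2 + self.sigma_v**2 + (
            self.sigma_s**2 if include_situation else 0.0
        )
        if denom == 0:
            raise ValueError("all variance components are zero")
        return self.sigma_r**2 / denom


@dataclass
class SimulatedDataset:
    """Generated data plus the realized ground-truth components."""

    config: SimulationConfig
    data: pd.DataFrame | None = None  # matrix form
    stream: SampleStream | None = None  # timestamped form
    truth: dict = field(default_factory=dict)

    def replicates(self) -> dict[str, np.ndarray]:
        """Matrix-form values pooled per participant (ICC input)."""
        if self.data is None:
            raise ValueError("matrix-form data not present")
        return {
            pid: grp["value"].to_numpy()
            for pid, grp in self.data.groupby("participant_id", sort=True)
        }


def _pid(i: int) -> str:
    return f"P{i + 1:03d}"


def bpm_study_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Heart-rate stream preset: quiet nights, noisier waking hours."""
    cfg = SimulationConfig(
        mu=70.0, sigma_r=8.0, sigma_s=3.0, sigma_v=2.0, sigma_v_wake=6.0,
        n_participants=10, wake_retention=0.10, zero_rate=0.0,
        outlier_rate=0.02, seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def rmssd_study_config(seed: int = 0, **overrides) -> SimulationConfig:
    """HRV (rMSSD) stream preset: volatile wakeful noise plus zero artifacts."""
    cfg = SimulationConfig(
        mu=50.0, sigma_r=15.0, sigma_s=5.0, sigma_v=8.0, sigma_v_wake=25.0,
        n_participants=10, wake_retention=0.07, zero_rate=0.1926,
        outlier_rate=0.02, seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


def simulate_components(config: SimulationConfig) -> SimulatedDataset:
    """Matrix-form draw: participants x situations x replicates, no timestamps."""
    rng = np.random.default_rng(config.seed)
    n, s, k = config.n_participants, config.n_situations, config.k_replicates
    r = rng.normal(0.0, config.sigma_r, size=n)
    sj = rng.normal(0.0, config.sigma_s, size=s)
    v = rng.normal(0.0, config.sigma_v, size=(n, s, k))
    noise_free = config.mu + r[:, None] + sj[None, :]
    values = noise_free[:, :, None] + v

    pids = [_pid(i) for i in range(n)]
    idx = pd.MultiIndex.from_product(
        [pids, range(s), range(k)], names=["participant_id", "situation", "replicate"]
    )
    data = pd.DataFrame({"value": values.ravel()}, index=idx).reset_index()
    truth = {
        "r": pd.Series(r, index=pids, name="r"),
        "s": pd.Series(sj, index=range(s), name="s"),
        "noise_free": pd.DataFrame(noise_free, index=pids, columns=range(s)),
        "residual": v,
    }
    return SimulatedDataset(config=config, data=data, truth=truth)


def _in_sleep_window(wall: pd.Series, window) -> np.ndarray:
    start, end = window
    t = wall.dt.time
    if start <= end:
        return ((t >= start) & (t < end)).to_numpy()
    return ((t >= start) | (t < end)).to_numpy()


def simulate_stream(
    config: SimulationConfig,
    n_days: int,
    metric: str = "bpm",
    start_date: datetime.date = _DEFAULT_START,
    offset_min: int = _DEFAULT_OFFSET_MIN,
) -> SimulatedDataset:
    """Timestamped stream on a 5-min grid with a nightly dense sleep block.

    Study day d runs noon-to-noon starting ``start_date + d``; every grid
    point inside the sleep window is emitted, wakeful grid points survive
    independently with probability ``wake_retention``.  Each (day, state)
    cell carries its own situation effect; residual noise uses ``sigma_v``
    during sleep and ``sigma_v_wake`` during wake.  Artifact injection
    (negative clipping to zero, zero-rate replacement for rMSSD, +4 SD
    spikes) happens after the truth records are stored.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    pids = [_pid(i) for i in range(n)]
    r = rng.normal(0.0, config.sigma_r, size=n)

    step = pd.Timedelta(minutes=config.sampling_period_min)
    day0_noon = pd.Timestamp(start_date) + pd.Timedelta(hours=12)
    grid_local = pd.Series(
        pd.date_range(day0_noon, day0_noon + pd.Timedelta(days=n_days), freq=step, inclusive="left")
    )
    sleep_mask = _in_sleep_window(grid_local, config.sleep_window)
    day_idx = ((grid_local - day0_noon) // pd.Timedelta(days=1)).to_numpy()
    n_grid = len(grid_local)

    frames = []
    situations = {}  # (pid, day, state) -> s effect
    for i, pid in enumerate(pids):
        s_sleep = rng.normal(0.0, config.sigma_s, size=n_days)
        s_wake = rng.normal(0.0, config.sigma_s, size=n_days)
        keep = sleep_mask | (rng.random(n_grid) < config.wake_retention)
        loc = grid_local[keep].reset_index(drop=True)
        asleep = sleep_mask[keep]
        days = day_idx[keep]
        s_eff = np.where(asleep, s_sleep[days], s_wake[days])
        sig = np.where(asleep, config.sigma_v, config.wake_sigma)
        v = rng.normal(0.0, 1.0, size=len(loc)) * sig
        value = config.mu + r[i] + s_eff + v
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "device_id": "sim",
                    "timestamp": (loc - pd.Timedelta(minutes=offset_min)).dt.tz_localize("UTC"),
                    "offset_min": offset_min,
                    "metric": metric,
                    "value": value,
                    "activity": "unlabeled",
                    "state": "unlabeled",
                    "_true_state": np.where(asleep, "sleep", "wake"),
                    "_day": days,
                    "_r": r[i],
                    "_s": s_eff,
                    "_v": v,
                }
            )
        )
        for d in range(n_days):
            situations[(pid, d, "sleep")] = float(s_sleep[d])
            situations[(pid, d, "wake")] = float(s_wake[d])

    full = pd.concat(frames, ignore_index=True)
    truth_records = full.copy()  # pre-artifact record-level truth

    # --- artifact injection ------------------------------------------------
    obs = full["value"].to_numpy().copy()
    obs[obs < 0] = 0.0  # physical floor; a negative read is a failed read
    if metric == "rmssd" and config.zero_rate > 0:
        zero_hit = rng.random(len(obs)) < config.zero_rate
        obs[zero_hit] = 0.0
    if config.outlier_rate > 0:
        for pid, grp in full.groupby("participant_id", sort=True):
            mean = grp["value"].mean()
            sd = grp["value"].std(ddof=1)
            hit = rng.random(len(grp)) < config.outlier_rate
            obs[grp.index[hit]] = mean + 4.0 * sd
    full = full.assign(value=obs).drop(columns=["_true_state", "_day", "_r", "_s", "_v"])

    stream = make_stream(full, provenance=f"simulate_stream(metric={metric}, seed={config.seed})")
    # nightly sleep means from the truth (for EMA coupling): keyed by the
    # morning date the night ends on (study day d ends on start_date + d + 1)
    sleep_truth = truth_records[truth_records["_true_state"] == "sleep"]
    night_means = (
        sleep_truth.groupby(["participant_id", "_day"])["value"].mean().reset_index()
    )
    night_means["morning_day"] = night_means["_day"].map(
        lambda d: start_date + datetime.timedelta(days=int(d) + 1)
    )
    truth = {
        "r": pd.Series(r, index=pids, name="r"),
        "situations": situations,
        "records": truth_records,
        "night_sleep_means": night_means,
        "start_date": start_date,
    }
    return SimulatedDataset(config=config, stream=stream, truth=truth)


_ITEM_BASE = {
    "happy": 6.0,
    "energetic": 6.0,
    "nervous": 3.0,
    "afraid": 2.0,
    "irritable": 3.0,
    "angry": 2.0,
    "pain": 2.0,
    "discomfort": 2.0,
}
_NEG = ("nervous", "afraid", "irritable", "angry")
_POS = ("happy", "energetic")


def simulate_ema(
    config: SimulationConfig,
    n_days: int,
    association: tuple[str, float] | None = None,
    coupled: SimulatedDataset | None = None,
    prompts_per_day: int = 6,
    start_date: datetime.date = _DEFAULT_START,
    offset_min: int = _DEFAULT_OFFSET_MIN,
) -> pd.DataFrame:
    """EMA prompts: 6/day at random times in 08:00-20:00, eight 1-10 items.

    With ``association=(metric, slope)`` and a coupled stream dataset, the
    negative-item means on day D shift by slope x (preceding night's true
    sleep mean - mu) before integer rounding and clipping, planting a
    next-day association that the lagged models can recover.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed % 2**31, 17]))
    pids = [_pid(i) for i in range(config.n_participants)]
    if association is not None:
        if coupled is None:
            raise ValueError("association requires a coupled simulated stream")
        _, slope = association
        nm = coupled.truth["night_sleep_means"]
        night = {
            (row.participant_id, row.morning_day): row.value for row in nm.itertuples()
        }
        mu = coupled.config.mu
    rows = []
    for pid in pids:
        trait_neg = rng.normal(0.0, 0.8)
        trait_pos = rng.normal(0.0, 0.8)
        for d in range(n_days):
            day = start_date + datetime.timedelta(days=d + 1)
            mood = rng.normal(0.0, 0.6)
            shift = 0.0
            if association is not None:
                base = night.get((pid, day))
                if base is not None:
                    shift = slope * (base - mu)
            minutes = np.sort(rng.integers(8 * 60, 20 * 60, size=prompts_per_day))
            for mnt in minutes:
                wall = pd.Timestamp(day) + pd.Timedelta(minutes=int(mnt))
                item_vals = {}
                for item, base_mean in _ITEM_BASE.items():
                    m = base_mean
                    if item in _NEG:
                        m += trait_neg + mood + shift
                    elif item in _POS:
                        m += trait_pos + mood
                    val = int(np.clip(np.round(m + rng.normal(0.0, 1.5)), 1, 10))
                    item_vals[item] = val
                rows.append(
                    {
                        "participant_id": pid,
                        "timestamp": (wall - pd.Timedelta(minutes=offset_min)).tz_localize("UTC"),
                        "offset_min": offset_min,
                        **item_vals,
                    }
                )
    out = pd.DataFrame(rows)
    for item in _ITEM_BASE:
        out[item] = out[item].astype(float)
    return out
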