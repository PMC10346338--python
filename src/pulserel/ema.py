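"""EMA affect scoring and lagged mixed-model associations with biometrics.

Each prompt's four negative items (irritable, afraid, nervous, angry) and two
positive items (happy, energetic) are averaged into prompt-level scores, then
averaged again within each calendar day.  Six mixed models link the daily
scores to daily biometrics: for each metric (BPM, rMSSD), the wakeful mean of
the concurrent day, the sleep mean of the preceding night (the one ending on
the morning of the affect day), and the sleep mean of the following night.
The biometric is the dependent variable, the two affect scores are the
predictors, the participant is a random intercept, and Bonferroni correction
uses the family of all six models.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SampleStream, local_wall_clock
from .lmm import DegenerateDesignError, fit_lmm

NEG_ITEMS = ("irritable", "afraid", "nervous", "angry")
POS_ITEMS = ("happy", "energetic")

MODEL_IDS = tuple(
    f"{metric}_{timing}"
    for metric in ("bpm", "rmssd")
    for timing in ("concurrent_wake", "preceding_night", "following_night")
)


@dataclass
class AssociationResult:
    """One lagged model's estimate for the negative-affect predictor.

    The positive-affect coefficient is carried alongside; the Bonferroni
    family size m covers the six models.
    """

    model_id: str
    beta: float
    t_stat: float
    df: float
    p_raw: float
    p_bonferroni: float
    n_observations: int
    beta_pos: float = np.nan
    p_raw_pos: float = np.nan
    p_bonferroni_pos: float = np.nan
    empty: bool = False
    converged: bool = True


@dataclass
class PromptScores:
    scores: pd.DataFrame  # participant_id, timestamp, offset_min, neg, pos
    skipped: list[tuple] = field(default_factory=list)  # (row, reason)


def score_prompts(records: pd.DataFrame) -> PromptScores:
    """Prompt-level negative/positive scores from the eight 1-10 items.

    A scale is scored when at least half its items are present (>= 2 of the
    4 negative items, >= 1 of the 2 positive items); prompts missing more
    than half of either scale are skipped and reported.  Pain and discomfort
    are carried in the data model but never scored.
    """
    rows = []
    skipped = []
    neg_vals = records[list(NEG_ITEMS)].to_numpy(dtype=float)
    pos_vals = records[list(POS_ITEMS)].to_numpy(dtype=float)
    n_neg = np.isfinite(neg_vals).sum(axis=1)
    n_pos = np.isfinite(pos_vals).sum(axis=1)
    neg_sum = np.where(np.isfinite(neg_vals), neg_vals, 0.0).sum(axis=1)
    pos_sum = np.where(np.isfinite(pos_vals), pos_vals, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        neg = neg_sum / n_neg
        pos = pos_sum / n_pos
    for i in range(len(records)):
        if n_neg[i] < 2 or n_pos[i] < 1:
            skipped.append((int(records.index[i]), "missing_majority_of_scale_items"))
            continue
        rows.append(
            (
                records["participant_id"].iloc[i],
                records["timestamp"].iloc[i],
                int(records["offset_min"].iloc[i]),
                float(neg[i]),
                float(pos[i]),
            )
        )
    return PromptScores(
        scores=pd.DataFrame(
            rows, columns=["participant_id", "timestamp", "offset_min", "neg", "pos"]
        ),
        skipped=skipped,
    )


def daily_affect(prompts: PromptScores) -> pd.DataFrame:
    """Per participant per calendar day, mean prompt-level neg/pos scores."""
    s = prompts.scores
    if s.empty:
        return pd.DataFrame(columns=["participant_id", "day", "neg_score", "pos_score", "n_prompts"])
    day = local_wall_clock(s).dt.date
    out = (
        s.assign(day=day)
        .groupby(["participant_id", "day"], sort=True)
        .agg(neg_score=("neg", "mean"), pos_score=("pos", "mean"), n_prompts=("neg", "size"))
        .reset_index()
    )
    return out


def daily_biometrics(stream: SampleStream) -> pd.DataFrame:
    """Daily mean biometric per (participant, day, state, metric).

    Wake records are keyed by the calendar day of their local timestamp;
    sleep records by the morning they end on (the noon-to-noon study day
    plus one), so a night is addressed by the day it precedes.
    """
    df = stream.records
    local = local_wall_clock(df)
    wake_day = local.dt.date
    sleep_day = (local - pd.Timedelta(hours=12)).dt.date + datetime.timedelta(days=1)
    day = wake_day.where(df["state"] != "sleep", sleep_day)
    labeled = df[df["state"].isin(("sleep", "wake"))]
    out = (
        labeled.assign(day=day[labeled.index])
        .groupby(["participant_id", "day", "state", "metric"], sort=True)["value"]
        .agg(mean_value="mean", n="size")
        .reset_index()
    )
    return out


def _model_rows(affect: pd.DataFrame, biometrics: pd.DataFrame, metric: str, timing: str) -> pd.DataFrame:
    if timing == "concurrent_wake":
        bio = biometrics[(biometrics["metric"] == metric) & (biometrics["state"] == "wake")]
        shift = 0
    else:
        bio = biometrics[(biometrics["metric"] == metric) & (biometrics["state"] == "sleep")]
        # sleep rows are keyed by the morning they end on:
        #   preceding night of affect day D  -> sleep day == D
        #   following night of affect day D  -> sleep day == D + 1
        shift = 0 if timing == "preceding_night" else 1
    aff = affect.copy()
    aff["bio_day"] = aff["day"] + datetime.timedelta(days=shift)
    merged = aff.merge(
        bio[["participant_id", "day", "mean_value"]],
        left_on=["participant_id", "bio_day"],
        right_on=["participant_id", "day"],
        suffixes=("", "_bio"),
    )
    return merged


def fit_lagged_models(
    affect: pd.DataFrame,
    biometrics: pd.DataFrame,
    m: int = 6,
    compute_df: bool = True,
) -> list[AssociationResult]:
    """Fit the six (metric x timing) lagged mixed models.

    Each model regresses the daily biometric on the negative and positive
    affect scores with a participant random intercept; p-values are
    Bonferroni-corrected with family size ``m``.
    """
    results = []
    for model_id in MODEL_IDS:
        metric, timing = model_id.split("_", 1)
        merged = _model_rows(affect, biometrics, metric, timing)
        enough = (
            len(merged) >= 3
            and merged["participant_id"].nunique() >= 2
            and (merged.groupby("participant_id").size() >= 2).sum() >= 2
        )
        if not enough:
            results.append(
                AssociationResult(
                    model_id=model_id, beta=np.nan, t_stat=np.nan, df=np.nan,
                    p_raw=np.nan, p_bonferroni=np.nan, n_observations=len(merged),
                    empty=True, converged=False,
                )
            )
            continue
        y = merged["mean_value"].to_numpy(dtype=float)
        X = np.column_stack(
            [np.ones(len(merged)), merged["neg_score"].to_numpy(), merged["pos_score"].to_numpy()]
        )
        try:
            fit = fit_lmm(
                y, X,
                groups={"participant": merged["participant_id"].to_numpy()},
                names=("intercept", "neg", "pos"),
                compute_df=compute_df,
            )
        except DegenerateDesignError:
            results.append(
                AssociationResult(
                    model_id=model_id, beta=np.nan, t_stat=np.nan, df=np.nan,
                    p_raw=np.nan, p_bonferroni=np.nan, n_observations=len(merged),
                    empty=True, converged=False,
                )
            )
            continue
        jn, jp = fit.names.index("neg"), fit.names.index("pos")
        results.append(
            AssociationResult(
                model_id=model_id,
                beta=float(fit.beta[jn]),
                t_stat=float(fit.t_stat[jn]),
                df=float(fit.df[jn]),
                p_raw=float(fit.p_value[jn]),
                p_bonferroni=bonferroni(float(fit.p_value[jn]), m),
                n_observations=fit.n_obs,
                beta_pos=float(fit.beta[jp]),
                p_raw_pos=float(fit.p_value[jp]),
                p_bonferroni_pos=bonferroni(float(fit.p_value[jp]), m),
                converged=fit.converged,
            )
        )
    return results


def bonferroni(p_raw: float, m: int = 6) -> float:
    """Bonferroni-corrected p-value: min(1, m * p_raw)."""
    if np.isnan(p_raw):
        return np.nan
    return min(1.0, m * p_raw)


def association_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Results as the tidy export table."""
    return pd.DataFrame(
        [
            (r.model_id, r.beta, r.t_stat, r.df, r.p_raw, r.p_bonferroni, r.n_observations)
            for r in results
        ],
        columns=["model_id", "beta", "t", "df", "p_raw", "p_bonferroni", "n"],
    )
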