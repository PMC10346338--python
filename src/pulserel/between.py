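"""Between-person reliability: one-way random-effects ANOVA and ICC.

The intraclass correlation treats each participant as a random draw from a
population, decomposing total variance into a between-participant component
sigma_r^2 and residual noise sigma_v^2; the population reliability is
rho = sigma_r^2 / (sigma_r^2 + sigma_v^2).  The sample estimator is the
one-way single-measure ICC(1,1),

    ICC = (MSBS - MSWS) / (MSBS + (k - 1) MSWS),

with MSBS/MSWS the between/within mean squares and k the replicate count.
Unbalanced designs substitute Searle's effective k0 and are flagged.
Confidence intervals use the Shrout-Fleiss one-way F bounds; the p-value is
the one-sided F test of zero ICC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .preprocessing import ConditionMeansTable


class InsufficientDataError(ValueError):
    pass


class UndefinedEstimateError(ValueError):
    pass


@dataclass
class AnovaDecomposition:
    """Mean-square bookkeeping for the one-way random-effects model."""

    msbs: float
    msws: float
    n: int  # participants
    k: float  # common replicate count, or Searle's k0 when unbalanced
    balanced: bool
    df_between: int
    df_within: int


@dataclass
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    confidence: float
    p_value: float
    form: str  # "single" or "average"
    n: int
    k: float
    balanced: bool


#: lower bin edges in increasing order, labels one longer than edges
DEFAULT_BINS = ((0.25, 0.40, 0.75), ("poor", "fair", "good", "excellent"))


def _replicate_lists(data) -> dict[str, np.ndarray]:
    if isinstance(data, ConditionMeansTable):
        return data.to_replicates()
    if isinstance(data, Mapping):
        return {str(k): np.asarray(v, dtype=float) for k, v in data.items()}
    if isinstance(data, Sequence):
        return {str(i): np.asarray(v, dtype=float) for i, v in enumerate(data)}
    raise TypeError("expected a ConditionMeansTable, mapping, or sequence of sequences")


def decompose_oneway(data) -> AnovaDecomposition:
    """One-way ANOVA decomposition over per-participant replicates.

    Accepts a :class:`ConditionMeansTable` (cells are the replicates) or a
    mapping/sequence of per-participant replicate lists.  Participants with
    fewer than 2 non-missing replicates are dropped with a warning.
    """
    groups = _replicate_lists(data)
    kept = {pid: v[np.isfinite(v)] for pid, v in groups.items()}
    dropped = [pid for pid, v in kept.items() if len(v) < 2]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} participant(s) with < 2 replicates: {dropped[:5]}",
            stacklevel=2,
        )
    kept = {pid: v for pid, v in kept.items() if len(v) >= 2}
    n = len(kept)
    if n < 2:
        raise InsufficientDataError(
            f"need >= 2 participants with >= 2 replicates each, have {n}"
        )
    ki = np.array([len(v) for v in kept.values()], dtype=float)
    means = np.array([v.mean() for v in kept.values()])
    total = float(ki.sum())
    grand = float(sum(v.sum() for v in kept.values()) / total)

    ssb = float(np.sum(ki * (means - grand) ** 2))
    ssw = float(sum(((v - v.mean()) ** 2).sum() for v in kept.values()))
    df_between = n - 1
    df_within = int(ki.sum()) - n
    balanced = bool(np.all(ki == ki[0]))
    if balanced:
        k = float(ki[0])
    else:
        # Searle's effective replicate count for unbalanced one-way designs
        k = float((total - float(np.sum(ki**2)) / total) / (n - 1))
    return AnovaDecomposition(
        msbs=ssb / df_between,
        msws=ssw / df_within,
        n=n,
        k=k,
        balanced=balanced,
        df_between=df_between,
        df_within=df_within,
    )


def _f_bounds(decomp: AnovaDecomposition, confidence: float) -> tuple[float, float, float]:
    """(F, FL, FU) for the one-way Shrout-Fleiss interval."""
    alpha = 1.0 - confidence
    df1, df2 = decomp.df_between, decomp.df_within
    if decomp.msws == 0:
        return np.inf, np.inf, np.inf
    f_obs = decomp.msbs / decomp.msws
    fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
    fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
    return f_obs, fl, fu


def _p_value(decomp: AnovaDecomposition) -> float:
    if decomp.msws == 0:
        return 0.0
    f_obs = decomp.msbs / decomp.msws
    return float(stats.f.sf(f_obs, decomp.df_between, decomp.df_within))


def icc_single(decomp: AnovaDecomposition, confidence: float = 0.95) -> ICCResult:
    """Single-measure ICC(1,1) with Shrout-Fleiss one-way CI and F test."""
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    msbs, msws, k = decomp.msbs, decomp.msws, decomp.k
    if msbs == 0 and msws == 0:
        raise UndefinedEstimateError("all observations identical: ICC undefined (0/0)")
    if msws == 0:
        estimate = 1.0
    else:
        estimate = (msbs - msws) / (msbs + (k - 1) * msws)
    _, fl, fu = _f_bounds(decomp, confidence)
    ci_low = (fl - 1) / (fl + k - 1) if np.isfinite(fl) else 1.0
    ci_high = (fu - 1) / (fu + k - 1) if np.isfinite(fu) else 1.0
    return ICCResult(
        estimate=float(estimate),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        confidence=confidence,
        p_value=_p_value(decomp),
        form="single",
        n=decomp.n,
        k=decomp.k,
        balanced=decomp.balanced,
    )


def icc_average(decomp: AnovaDecomposition, confidence: float = 0.95) -> ICCResult:
    """Average-measure ICC(1,k): reliability of the k-replicate mean."""
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    msbs, msws = decomp.msbs, decomp.msws
    if msbs == 0:
        raise UndefinedEstimateError("MSBS = 0: average-measure ICC undefined")
    estimate = (msbs - msws) / msbs
    _, fl, fu = _f_bounds(decomp, confidence)
    ci_low = 1 - 1 / fl if np.isfinite(fl) else 1.0
    ci_high = 1 - 1 / fu if np.isfinite(fu) else 1.0
    return ICCResult(
        estimate=float(estimate),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        confidence=confidence,
        p_value=_p_value(decomp),
        form="average",
        n=decomp.n,
        k=decomp.k,
        balanced=decomp.balanced,
    )


def classify_icc(estimate: float, bins=DEFAULT_BINS) -> str:
    """Qualitative reliability label for an ICC estimate.

    Default bins: >= 0.75 excellent, [0.40, 0.75) good, [0.25, 0.40) fair,
    < 0.25 poor.  Custom bins are (ascending lower edges, labels), with one
    more label than edge.
    """
    edges, labels = bins
    if len(labels) != len(edges) + 1:
        raise ValueError("need exactly one more label than bin edge")
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError(f"bin edges must be strictly increasing, got {edges}")
    if not -1.0 <= estimate <= 1.0:
        raise ValueError(f"ICC estimate {estimate} outside [-1, 1]")
    idx = int(np.searchsorted(edges, estimate, side="right"))
    return labels[idx]
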