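"""Independent brute-force oracles used only by the test suite.

These deliberately use explicit loops and the defining formulas, staying
independent of the implementation paths they check.
"""

import numpy as np


def anova_oneway_brute(groups):
    """One-way ANOVA mean squares by explicit double loops.

    groups: list of per-participant replicate lists (balanced or not).
    Returns (msbs, msws, n, k_or_k0).
    """
    n = len(groups)
    ki = [len(g) for g in groups]
    total = sum(ki)
    grand = sum(x for g in groups for x in g) / total
    ssb = 0.0
    for g in groups:
        mean_i = sum(g) / len(g)
        ssb += len(g) * (mean_i - grand) ** 2
    msbs = ssb / (n - 1)
    ssw = 0.0
    for g in groups:
        mean_i = sum(g) / len(g)
        for x in g:
            ssw += (x - mean_i) ** 2
    msws = ssw / sum(k - 1 for k in ki)
    if len(set(ki)) == 1:
        k = ki[0]
    else:
        k = (total - sum(k * k for k in ki) / total) / (n - 1)
    return msbs, msws, n, k


def icc1_brute(groups):
    """Single-measure one-way ICC from the brute-force mean squares."""
    msbs, msws, _, k = anova_oneway_brute(groups)
    return (msbs - msws) / (msbs + (k - 1) * msws)


def dense_runs_brute(times, max_gap):
    """All maximal runs of consecutive instants with gaps <= max_gap.

    times: sorted sequence of timestamps. Returns list of (start_idx, end_idx)
    inclusive index pairs, found by a naive scan.
    """
    runs = []
    i = 0
    n = len(times)
    while i < n:
        j = i
        while j + 1 < n and times[j + 1] - times[j] <= max_gap:
            j += 1
        runs.append((i, j))
        i = j + 1
    return runs


def best_sleep_run_brute(times, min_duration, max_gap):
    """Longest qualifying run (span >= min_duration), earliest on ties.

    Returns (start_time, end_time, n_samples) or None.
    """
    best = None
    for i, j in dense_runs_brute(times, max_gap):
        span = times[j] - times[i]
        if span < min_duration:
            continue
        if best is None or span > (best[1] - best[0]):
            best = (times[i], times[j], j - i + 1)
    return best


def mean_sd_brute(values):
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, np.sqrt(var)
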