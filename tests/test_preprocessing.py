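import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulserel.preprocessing import (
    condition_means,
    filter_log_frame,
    remove_outlier_samples,
    remove_zero_samples,
)

from conftest import series_stream, stream_from_rows
from oracles import mean_sd_brute


def log_entry(stream, rule_prefix, metric):
    matches = [e for e in stream.filter_log if e.rule.startswith(rule_prefix) and e.metric == metric]
    assert matches
    return matches[-1]


class TestZeroFilter:
    def test_removes_zeros_and_logs_fraction(self):
        s = series_stream("A", "bpm", [0, 55, 0, 60])
        out = remove_zero_samples(s)
        assert list(out.records["value"]) == [55.0, 60.0]
        e = log_entry(out, "zero_filter", "bpm")
        assert (e.removed, e.fraction) == (2, 0.5)

    def test_no_zeros_is_identity_with_zero_fraction(self):
        s = series_stream("A", "bpm", [55, 60])
        out = remove_zero_samples(s)
        assert out.records["value"].tolist() == [55.0, 60.0]
        assert log_entry(out, "zero_filter", "bpm").fraction == 0.0

    def test_idempotent(self):
        s = series_stream("A", "rmssd", [0, 30, 40, 0])
        once = remove_zero_samples(s)
        twice = remove_zero_samples(once)
        assert once.records["value"].tolist() == twice.records["value"].tolist()
        assert log_entry(twice, "zero_filter", "rmssd").removed in (0, 2)

    def test_logged_fraction_matches_planted_rate(self):
        # a 19.26% zero rate must be logged as 0.1926
        values = [0.0] * 1926 + [50.0] * 8074
        s = series_stream("A", "rmssd", values)
        out = remove_zero_samples(s)
        assert log_entry(out, "zero_filter", "rmssd").fraction == pytest.approx(0.1926)

    def test_all_zero_metric_warns_and_empties(self):
        s = series_stream("A", "rmssd", [0, 0, 0])
        with pytest.warns(UserWarning, match="empty"):
            out = remove_zero_samples(s)
        assert len(out) == 0


class TestOutlierFilter:
    def test_hand_computed_bound(self):
        values = [60, 61, 62, 63, 64, 100]
        mean, sd = mean_sd_brute(values)
        assert mean == pytest.approx(68.3333, abs=1e-3)
        assert sd == pytest.approx(15.578, abs=1e-2)
        s = series_stream("A", "bpm", values)
        out = remove_outlier_samples(s, n_sd=2)
        assert out.records["value"].tolist() == [60, 61, 62, 63, 64]
        assert log_entry(out, "outlier_filter", "bpm").removed == 1

    def test_constant_series_untouched(self):
        s = series_stream("A", "bpm", [70, 70, 70])
        out = remove_outlier_samples(s)
        assert len(out) == 3

    def test_strict_inequality_keeps_boundary_value(self):
        values = [10.0, 20.0, 30.0]  # sd=10, mean=20: 40 would sit exactly at 2 SD
        s = series_stream("A", "bpm", values + [40.0])
        # recompute: with 40 included mean=25, sd != 10; craft directly instead
        out = remove_outlier_samples(series_stream("A", "bpm", values), n_sd=1.0)
        # bounds are mean +- 10, all values exactly at or within -> kept
        assert out.records["value"].tolist() == values

    def test_participants_judged_independently(self):
        rows = [("A", "bpm", f"2023-03-06T10:{m:02d}:00-07:00", v) for m, v in
                enumerate([60, 61, 62, 63, 64, 100])]
        rows += [("B", "bpm", f"2023-03-06T10:{m:02d}:00-07:00", v) for m, v in
                 enumerate([100, 101, 102, 103])]
        s = stream_from_rows(rows)
        out = remove_outlier_samples(s)
        b = out.records[out.records["participant_id"] == "B"]
        assert len(b) == 4  # B's 100s are normal for B
        a = out.records[out.records["participant_id"] == "A"]
        assert 100 not in a["value"].tolist()

    def test_short_series_skipped_with_warning(self):
        s = series_stream("A", "bpm", [60, 200])
        with pytest.warns(UserWarning, match="SD unstable"):
            out = remove_outlier_samples(s)
        assert len(out) == 2

    @given(st.lists(st.floats(min_value=1, max_value=200), min_size=3, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_conservation(self, values):
        s = series_stream("A", "bpm", values)
        out = remove_outlier_samples(remove_zero_samples(s))
        removed = sum(e.removed for e in out.filter_log)
        assert removed + len(out) == len(s)


class TestConditionMeans:
    def test_cell_means_and_missing_cells(self):
        s = stream_from_rows(
            [
                ("A", "bpm", "2023-03-06T10:00:00-07:00", 60, "rest"),
                ("A", "bpm", "2023-03-06T10:05:00-07:00", 62, "rest"),
                ("A", "bpm", "2023-03-06T10:10:00-07:00", 80, "walk"),
                ("B", "bpm", "2023-03-06T10:00:00-07:00", 55, "rest"),
            ]
        )
        t = condition_means(s, "activity")
        assert t.means.loc["A", "rest"] == 61
        assert t.means.loc["A", "walk"] == 80
        assert t.counts.loc["B", "walk"] == 0
        assert np.isnan(t.means.loc["B", "walk"])
        # missing iff count zero
        assert ((t.counts == 0) == t.means.isna()).all().all()

    def test_grid_shape(self):
        rows = []
        for pid in "ABC":
            for j, act in enumerate(["a1", "a2", "a3", "a4", "a5"]):
                rows.append((pid, "bpm", f"2023-03-06T1{j}:00:00-07:00", 60 + j, act))
        t = condition_means(stream_from_rows(rows), "activity")
        assert t.means.shape == (3, 5)

    def test_unlabeled_condition_rejected(self):
        s = series_stream("A", "bpm", [60, 61])
        with pytest.raises(ValueError, match="unlabeled"):
            condition_means(s, "activity")

    def test_multi_metric_requires_selector(self):
        s = stream_from_rows(
            [
                ("A", "bpm", "2023-03-06T10:00:00-07:00", 60, "rest"),
                ("A", "rmssd", "2023-03-06T10:00:00-07:00", 40, "rest"),
            ]
        )
        with pytest.raises(ValueError, match="metric"):
            condition_means(s, "activity")
        t = condition_means(s, "activity", metric="rmssd")
        assert t.means.loc["A", "rest"] == 40


def test_filter_log_frame_columns():
    s = remove_zero_samples(series_stream("A", "bpm", [0, 60]))
    df = filter_log_frame(s)
    assert list(df.columns) == ["rule", "metric", "removed", "fraction"]
    assert df["fraction"].between(0, 1).all()
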