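import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulserel.lmm import DegenerateDesignError
from pulserel.synthetic import SimulationConfig, simulate_stream
from pulserel.segmentation import detect_sleep_periods, label_state
from pulserel.within import (
    fit_split_model,
    random_split_distribution,
    split_random,
    split_time_sensitive,
)

from conftest import series_stream, stream_from_rows


def labeled_sim_stream(sigma_v=2.0, sigma_v_wake=None, seed=4, n_days=5, n_participants=6,
                       sigma_s=3.0, wake_retention=0.15):
    cfg = SimulationConfig(
        mu=70, sigma_r=8, sigma_s=sigma_s, sigma_v=sigma_v, sigma_v_wake=sigma_v_wake,
        n_participants=n_participants, wake_retention=wake_retention, seed=seed,
    )
    ds = simulate_stream(cfg, n_days=n_days)
    ivs = detect_sleep_periods(ds.stream)
    return label_state(ds.stream, ivs)


class TestTimeSensitiveSplit:
    def test_even_count_halves(self):
        s = series_stream("A", "bpm", [70, 72, 74, 76], step_min=5)
        s.records["activity"] = "rest"
        pairs = split_time_sensitive(s, ("activity",))
        row = pairs.table.iloc[0]
        assert (row["criterion_mean"], row["predictor_mean"]) == (72.0, 74.0)
        assert (row["n_odd"], row["n_even"]) == (2, 2)

    def test_odd_count_extra_goes_to_odd_half(self):
        s = series_stream("A", "bpm", [70, 72, 74, 76, 78])
        s.records["activity"] = "rest"
        pairs = split_time_sensitive(s, ("activity",))
        row = pairs.table.iloc[0]
        assert row["criterion_mean"] == pytest.approx((70 + 74 + 78) / 3)
        assert row["predictor_mean"] == pytest.approx((72 + 76) / 2)
        assert abs(row["n_odd"] - row["n_even"]) == 1

    def test_single_sample_unit_dropped_and_reported(self):
        s = stream_from_rows(
            [
                ("A", "bpm", "2023-03-06T10:00:00-07:00", 60, "rest"),
                ("A", "bpm", "2023-03-06T10:05:00-07:00", 61, "rest"),
                ("A", "bpm", "2023-03-06T11:00:00-07:00", 90, "walk"),
            ]
        )
        pairs = split_time_sensitive(s, ("activity",))
        assert len(pairs) == 1
        assert pairs.dropped == [("A", "walk")]


class TestRandomSplit:
    def test_constant_unit_always_equal_halves(self):
        s = series_stream("A", "bpm", [5, 5, 5, 5])
        s.records["activity"] = "rest"
        pairs = split_random(s, ("activity",), seed=3)
        row = pairs.table.iloc[0]
        assert row["criterion_mean"] == row["predictor_mean"] == 5.0

    def test_partition_sizes_and_conservation(self):
        s = series_stream("A", "bpm", [1, 2, 3])
        s.records["activity"] = "rest"
        pairs = split_random(s, ("activity",), seed=0)
        row = pairs.table.iloc[0]
        assert sorted([row["n_odd"], row["n_even"]]) == [1, 2]

    def test_same_seed_reproduces_partition(self):
        s = labeled_sim_stream()
        a = split_random(s, "study2", seed=42, metric="bpm")
        b = split_random(s, "study2", seed=42, metric="bpm")
        pd.testing.assert_frame_equal(a.table, b.table)
        c = split_random(s, "study2", seed=43, metric="bpm")
        assert not a.table["criterion_mean"].equals(c.table["criterion_mean"])

    @given(m=st.integers(2, 25), seed=st.integers(0, 100))
    @settings(max_examples=40, deadline=None)
    def test_half_sizes_always_balanced(self, m, seed):
        s = series_stream("A", "bpm", list(np.arange(1.0, m + 1)))
        s.records["activity"] = "rest"
        pairs = split_random(s, ("activity",), seed=seed)
        row = pairs.table.iloc[0]
        assert row["n_odd"] + row["n_even"] == m
        assert abs(row["n_odd"] - row["n_even"]) <= 1


class TestSplitModel:
    def test_identity_pairs_give_slope_one(self):
        # zero residual noise and no wakeful stragglers adjoining the sleep
        # runs: both halves equal the unit mean by construction
        s = labeled_sim_stream(sigma_v=0.0, sigma_v_wake=0.0, wake_retention=0.0)
        pairs = split_time_sensitive(s, "study2", metric="bpm")
        fit = fit_split_model(pairs, ("participant",))
        assert fit.beta == pytest.approx(1.0, abs=1e-6)
        assert fit.intercept == pytest.approx(0.0, abs=1e-4)
        assert fit.converged

    def test_constant_predictor_rejected(self):
        table = pd.DataFrame(
            {
                "participant_id": ["A", "A", "B", "B"],
                "study_day": ["d1", "d2", "d1", "d2"],
                "state": ["wake"] * 4,
                "predictor_mean": [5.0, 5.0, 5.0, 5.0],
                "criterion_mean": [5.0, 6.0, 7.0, 8.0],
                "n_odd": [2] * 4,
                "n_even": [2] * 4,
            }
        )
        from pulserel.within import SplitPairTable

        pairs = SplitPairTable(table=table, unit_cols=("study_day", "state"))
        with pytest.raises(DegenerateDesignError, match="constant"):
            fit_split_model(pairs)

    def test_too_few_pairs_rejected(self):
        from pulserel.within import SplitPairTable

        pairs = SplitPairTable(
            table=pd.DataFrame(
                {
                    "participant_id": ["A", "B"],
                    "predictor_mean": [1.0, 2.0],
                    "criterion_mean": [1.0, 2.0],
                    "n_odd": [1, 1],
                    "n_even": [1, 1],
                }
            ),
            unit_cols=(),
        )
        with pytest.raises(DegenerateDesignError):
            fit_split_model(pairs)


class TestRandomSplitDistribution:
    def test_noiseless_distribution_degenerate_at_one(self):
        s = labeled_sim_stream(sigma_v=0.0, sigma_v_wake=0.0, wake_retention=0.0)
        summary = random_split_distribution(
            s, "study2", ("participant",), n_iterations=50, master_seed=1, metric="bpm"
        )
        assert summary.mean_beta == pytest.approx(1.0, abs=1e-9)
        assert summary.sd_beta == pytest.approx(0.0, abs=1e-9)
        assert summary.n_failed == 0

    def test_same_master_seed_bit_identical(self):
        s = labeled_sim_stream()
        kw = dict(n_iterations=20, master_seed=9, metric="bpm")
        a = random_split_distribution(s, "study2", ("participant",), **kw)
        b = random_split_distribution(s, "study2", ("participant",), **kw)
        assert a.mean_beta == b.mean_beta and a.sd_beta == b.sd_beta
        assert np.array_equal(a.betas, b.betas)

    def test_conservation_per_unit(self):
        s = labeled_sim_stream()
        pairs = split_random(s, "study2", seed=5, metric="bpm")
        sub = s.records[s.records["metric"] == "bpm"]
        from pulserel.segmentation import assign_study_day

        sd = assign_study_day(s.with_records(sub)).astype(str)
        counts = sub.groupby([sub["participant_id"], sd, sub["state"]]).size()
        for _, row in pairs.table.iterrows():
            key = (row["participant_id"], row["study_day"], row["state"])
            assert row["n_odd"] + row["n_even"] == counts.loc[key]

    def test_noise_monotonicity(self):
        betas = []
        for sigma_v in (1.0, 4.0, 12.0):
            s = labeled_sim_stream(sigma_v=sigma_v, sigma_v_wake=sigma_v, seed=8)
            summ = random_split_distribution(
                s, "study2", ("participant",), n_iterations=60, master_seed=2, metric="bpm"
            )
            betas.append(summ.mean_beta)
        assert betas[0] > betas[1] > betas[2] - 0.02  # Monte-Carlo slack on the last step

    def test_time_sensitive_within_random_distribution_for_iid_units(self):
        # without serial structure the odd/even split is exchangeable with a
        # random split, so its beta should fall inside the central mass
        hits = 0
        n_data = 10
        for seed in range(n_data):
            s = labeled_sim_stream(sigma_v=4.0, sigma_v_wake=4.0, seed=100 + seed,
                                   n_days=4, n_participants=5)
            ts = fit_split_model(
                split_time_sensitive(s, "study2", metric="bpm"), ("participant",),
                compute_df=False,
            )
            summ = random_split_distribution(
                s, "study2", ("participant",), n_iterations=80, master_seed=seed,
                metric="bpm",
            )
            lo, hi = np.quantile(summ.betas, [0.025, 0.975])
            hits += lo <= ts.beta <= hi
        assert hits >= 0.9 * n_data

    def test_swap_symmetry_within_standard_error(self):
        s = labeled_sim_stream(sigma_v=3.0, sigma_v_wake=3.0, seed=21)
        pairs = split_time_sensitive(s, "study2", metric="bpm")
        fwd = fit_split_model(pairs, ("participant",))
        swapped = pairs.table.rename(
            columns={"predictor_mean": "criterion_mean", "criterion_mean": "predictor_mean"}
        )
        from pulserel.within import SplitPairTable

        rev = fit_split_model(
            SplitPairTable(table=swapped, unit_cols=pairs.unit_cols), ("participant",)
        )
        assert abs(fwd.beta - rev.beta) <= 2 * max(fwd.se, rev.se)
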