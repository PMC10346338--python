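import numpy as np
import pingouin as pg
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulserel.between import (
    InsufficientDataError,
    UndefinedEstimateError,
    classify_icc,
    decompose_oneway,
    icc_average,
    icc_single,
)
from pulserel.synthetic import SimulationConfig, simulate_components

from oracles import icc1_brute


class TestDecompose:
    def test_balanced_hand_example(self):
        d = decompose_oneway({"A": [1, 2], "B": [3, 4]})
        assert (d.msbs, d.msws, d.n, d.k, d.balanced) == (4.0, 0.5, 2, 2.0, True)

    def test_constant_data(self):
        d = decompose_oneway({"A": [5, 5], "B": [5, 5]})
        assert d.msbs == 0 and d.msws == 0

    def test_unbalanced_searle_k0(self):
        d = decompose_oneway({"A": [1, 2], "B": [3, 4, 5]})
        assert not d.balanced
        assert d.k == pytest.approx(5 - 13 / 5)  # (1/(n-1)) (sum k - sum k^2/sum k)

    def test_single_replicate_participants_dropped(self):
        with pytest.warns(UserWarning, match="dropping"):
            d = decompose_oneway({"A": [1, 2], "B": [3, 4], "C": [9]})
        assert d.n == 2

    def test_too_few_participants(self):
        with pytest.raises(InsufficientDataError):
            decompose_oneway({"A": [1, 2]})


class TestIccEstimates:
    def test_single_hand_value(self):
        res = icc_single(decompose_oneway({"A": [1, 2], "B": [3, 4]}))
        assert res.estimate == pytest.approx(3.5 / 4.5)  # (4-0.5)/(4+0.5)

    def test_perfect_reliability(self):
        res = icc_single(decompose_oneway({"A": [1, 1], "B": [2, 2]}))
        assert res.estimate == 1.0 and res.p_value == 0.0

    def test_algebraic_lower_bound(self):
        # MSBS = 0: participants identical in mean, noise within
        res = icc_single(decompose_oneway({"A": [0, 2], "B": [0, 2]}))
        assert res.estimate == pytest.approx(-1.0)  # -1/(k-1) with k=2

    def test_undefined_when_all_identical(self):
        with pytest.raises(UndefinedEstimateError):
            icc_single(decompose_oneway({"A": [5, 5], "B": [5, 5]}))

    def test_average_hand_value_and_spearman_brown(self):
        d = decompose_oneway({"A": [1, 2], "B": [3, 4]})
        rho1 = icc_single(d).estimate
        rhok = icc_average(d).estimate
        assert rhok == pytest.approx(0.875)
        k = d.k
        assert rhok == pytest.approx(k * rho1 / (1 + (k - 1) * rho1))

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(0)
        groups = {f"P{i}": rng.normal(i, 1.0, size=4) for i in range(8)}
        for fn in (icc_single, icc_average):
            res = fn(decompose_oneway(groups))
            assert res.ci_low <= res.estimate <= res.ci_high


class TestOracleEquivalence:
    def test_brute_force_and_pingouin_agree(self, rng):
        for trial in range(100):
            n = int(rng.integers(3, 7))
            k = int(rng.integers(2, 5))
            data = rng.normal(0, 1, size=(n, k)) + rng.normal(0, 1, size=(n, 1))
            groups = {f"P{i}": data[i] for i in range(n)}
            ours = icc_single(decompose_oneway(groups)).estimate
            assert ours == pytest.approx(icc1_brute(list(data)), abs=1e-10)
            long = pd.DataFrame(
                {
                    "targets": np.repeat(np.arange(n), k),
                    "raters": np.tile(np.arange(k), n),
                    "ratings": data.ravel(),
                }
            )
            icc_pg = pg.intraclass_corr(
                data=long, targets="targets", raters="raters", ratings="ratings"
            )
            ref = float(icc_pg.loc[icc_pg["Type"] == "ICC(1,1)", "ICC"].iloc[0])
            assert ours == pytest.approx(ref, abs=1e-8)

    def test_ci_matches_pingouin(self, rng):
        n, k = 10, 4
        data = rng.normal(0, 1, size=(n, k)) + rng.normal(0, 2, size=(n, 1))
        res = icc_single(decompose_oneway({f"P{i}": data[i] for i in range(n)}))
        long = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(n), k),
                "raters": np.tile(np.arange(k), n),
                "ratings": data.ravel(),
            }
        )
        icc_pg = pg.intraclass_corr(data=long, targets="targets", raters="raters", ratings="ratings")
        lo, hi = icc_pg.loc[icc_pg["Type"] == "ICC(1,1)", "CI95"].iloc[0]
        # pingouin prints the interval rounded to 2 decimals
        assert res.ci_low == pytest.approx(lo, abs=6e-3)
        assert res.ci_high == pytest.approx(hi, abs=6e-3)


class TestInvariances:
    @given(
        shift=st.floats(-50, 50, allow_nan=False),
        scale=st.floats(0.1, 20, allow_nan=False),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=40, deadline=None)
    def test_location_scale_invariance(self, shift, scale, seed):
        rng = np.random.default_rng(seed)
        data = rng.normal(0, 1, size=(5, 3)) + rng.normal(0, 1, size=(5, 1))
        base = icc1(data)
        transformed = icc1(data * scale + shift)
        assert transformed == pytest.approx(base, abs=1e-12)

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_permutation_invariance_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.normal(0, 1, size=(5, 4)) + rng.normal(0, 1.5, size=(5, 1))
        base = icc1(data)
        perm = data[rng.permutation(5)][:, rng.permutation(4)]
        # replicate order shuffled independently per participant
        perm = np.stack([row[rng.permutation(4)] for row in perm])
        assert icc1(perm) == pytest.approx(base, abs=1e-12)
        k = data.shape[1]
        assert -1 / (k - 1) - 1e-12 <= base <= 1 + 1e-12


def icc1(matrix):
    return icc_single(decompose_oneway({str(i): row for i, row in enumerate(matrix)})).estimate


class TestParameterRecovery:
    def test_recovers_population_icc(self):
        cfg = SimulationConfig(
            mu=0, sigma_r=1, sigma_s=0, sigma_v=1,
            n_participants=500, n_situations=8, k_replicates=1, seed=11,
        )
        ds = simulate_components(cfg)
        est = icc_single(decompose_oneway(ds.replicates())).estimate
        assert est == pytest.approx(cfg.population_icc(), abs=0.05)

    def test_zero_noise_gives_exactly_one(self):
        cfg = SimulationConfig(
            mu=0, sigma_r=1, sigma_s=0, sigma_v=0,
            n_participants=20, n_situations=4, k_replicates=1, seed=1,
        )
        est = icc_single(decompose_oneway(simulate_components(cfg).replicates())).estimate
        assert est == 1.0


class TestClassification:
    @pytest.mark.parametrize(
        "value,label",
        [(0.80, "excellent"), (0.75, "excellent"), (0.65, "good"), (0.40, "good"),
         (0.38, "fair"), (0.25, "fair"), (0.10, "poor"), (-0.5, "poor")],
    )
    def test_default_bins(self, value, label):
        assert classify_icc(value) == label

    def test_non_monotone_bins_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            classify_icc(0.5, bins=((0.4, 0.2), ("a", "b", "c")))
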