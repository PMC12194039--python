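"""Binning, Pearson, Victor-Purpura and summary-statistics tests.

The Victor-Purpura implementation is checked against an independent
brute-force oracle that enumerates every order-preserving partial matching
between the two trains (cost = unmatched spikes + q*|dt| per matched pair).
"""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spikempc.metrics import (
    MetricConfig,
    MetricError,
    SpikeTrain,
    bin_downsample,
    pearson,
    rates_to_spikes,
    summarize,
    victor_purpura,
)
from spikempc.model import TimeSeries


def vp_brute_force(a, b, q):
    """Exhaustive matching enumeration; independent of the DP implementation."""
    a, b = list(a), list(b)
    best = np.inf
    for k in range(min(len(a), len(b)) + 1):
        for ia in combinations(range(len(a)), k):
            for ib in combinations(range(len(b)), k):
                cost = (len(a) - k) + (len(b) - k)
                cost += sum(q * abs(a[i] - b[j]) for i, j in zip(ia, ib))
                best = min(best, cost)
    return best


class TestBinning:
    def test_block_sum_of_rate_mass(self):
        ts = TimeSeries(values=np.array([1, 1, 1, 1, 2, 2, 2, 2], float), dt=1.0)
        assert np.array_equal(bin_downsample(ts, 4), [4.0, 8.0])

    def test_spike_counts_per_40ms_bin(self):
        train = SpikeTrain(times=np.array([0.005, 0.012, 0.095]))
        counts = bin_downsample(train, 4, native_dt=0.01, n_samples=12)
        assert np.array_equal(counts, [2, 0, 1])

    def test_factor_one_is_identity_on_counts(self):
        train = SpikeTrain(times=np.array([0.005, 0.025, 0.028]))
        counts = bin_downsample(train, 1, native_dt=0.01, n_samples=4)
        assert np.array_equal(counts, [1, 0, 2, 0])

    def test_partial_tail_dropped_with_warning(self):
        ts = TimeSeries(values=np.ones(10), dt=1.0)
        with pytest.warns(UserWarning, match="tail"):
            out = bin_downsample(ts, 4)
        assert np.array_equal(out, [4.0, 4.0])

    def test_invalid_factor(self):
        with pytest.raises(MetricError):
            bin_downsample(TimeSeries(values=np.ones(4), dt=1.0), 0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6), factor=st.integers(1, 5))
    def test_total_count_conserved_up_to_tail(self, seed, factor):
        rng = np.random.default_rng(seed)
        n = 40
        counts = rng.poisson(0.3, n)
        train = SpikeTrain.from_counts(counts, 0.01)
        binned = bin_downsample(train, factor, native_dt=0.01, n_samples=n)
        kept = (n // factor) * factor
        assert binned.sum() == counts[:kept].sum()


class TestPearson:
    def test_exact_linear_relation(self):
        assert pearson([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)

    def test_exact_anticorrelation(self):
        assert pearson([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_textbook_hand_computation(self):
        # means 0.75/0.75, covariance sum -2.25, variances 2.75 -> r = -9/11
        assert pearson([1, 0, 2, 0], [0, 1, 0, 2]) == pytest.approx(-9 / 11)

    def test_constant_input_undefined(self):
        with pytest.raises(MetricError):
            pearson([1, 1, 1], [1, 2, 3])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10**6),
        lam=st.floats(0.1, 20),
        mu=st.floats(-5, 5),
    )
    def test_positive_affine_invariance(self, seed, lam, mu):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=20)
        b = rng.normal(size=20)
        assert pearson(a, lam * b + mu) == pytest.approx(pearson(a, b), abs=1e-9)


class TestVictorPurpura:
    CFG = MetricConfig()  # unit move cost per 10 ms step

    def test_identical_trains_zero(self):
        t = SpikeTrain(times=np.array([0.1, 0.5, 0.9]))
        assert victor_purpura(t, t, self.CFG) == 0.0

    def test_empty_versus_three_spikes(self):
        empty = SpikeTrain(times=np.array([]))
        three = SpikeTrain(times=np.array([0.1, 0.2, 0.3]))
        assert victor_purpura(empty, three, self.CFG) == 3.0

    def test_single_step_shift_costs_one(self):
        a = SpikeTrain(times=np.array([0.100]))
        b = SpikeTrain(times=np.array([0.110]))
        assert victor_purpura(a, b, self.CFG) == pytest.approx(1.0)

    def test_matches_brute_force_on_small_trains(self):
        """DP vs exhaustive matching on all trains of <= 3 spikes on a grid."""
        grid = [0.01, 0.02, 0.05, 0.09, 0.13]
        q = self.CFG.vp_shift_cost_per_step / self.CFG.native_dt
        trains = [c for k in range(4) for c in combinations(grid, k)]
        for ta in trains:
            for tb in trains:
                got = victor_purpura(
                    SpikeTrain(times=np.array(ta)), SpikeTrain(times=np.array(tb)), self.CFG
                )
                assert got == pytest.approx(vp_brute_force(ta, tb, q)), (ta, tb)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_metric_axioms(self, seed):
        rng = np.random.default_rng(seed)
        trains = [
            SpikeTrain(times=np.sort(rng.uniform(0, 0.5, rng.integers(0, 6))))
            for _ in range(3)
        ]
        a, b, c = trains
        dab = victor_purpura(a, b, self.CFG)
        assert dab == pytest.approx(victor_purpura(b, a, self.CFG))  # symmetry
        assert victor_purpura(a, a, self.CFG) == 0.0  # identity
        assert dab <= len(a) + len(b) + 1e-12  # delete/insert bound
        dac = victor_purpura(a, c, self.CFG)
        dcb = victor_purpura(c, b, self.CFG)
        assert dab <= dac + dcb + 1e-9  # triangle inequality


class TestRatesToSpikes:
    def test_zero_rate_empty_train(self):
        out = rates_to_spikes(TimeSeries(values=np.zeros(40), dt=0.01))
        assert len(out) == 0

    def test_rounding_rule_emits_single_spike(self):
        # one 40 ms bin carrying 0.96 expected spikes -> 1 spike at center
        vals = np.zeros(8)
        vals[4:8] = 24.0  # mass = 24 Hz * 4 * 0.01 s = 0.96
        out = rates_to_spikes(TimeSeries(values=vals, dt=0.01))
        assert len(out) == 1
        assert out.times[0] == pytest.approx(0.06)  # center of second bin

    def test_exact_drive_roundtrip_preserves_counts(self):
        from spikempc.synthetic import spikes_to_drive

        train = SpikeTrain(times=np.array([0.015, 0.055, 0.058, 0.115]))
        drive = spikes_to_drive(train, 0.01, 16)
        out = rates_to_spikes(drive)
        assert len(out) == len(train)


class TestSummarize:
    def test_identical_scores_zero_std(self):
        table = summarize({"d1": [0.5, 0.5]})
        row = table[table.group == "d1"].iloc[0]
        assert row["std"] == 0.0 and not row["degenerate"]

    def test_two_groups_and_pooled(self):
        table = summarize({"a": [1.0, 3.0], "b": [5.0, 7.0]})
        stds = table.set_index("group")["std"]
        assert stds["a"] == pytest.approx(np.sqrt(2))
        assert stds["b"] == pytest.approx(np.sqrt(2))
        assert stds["all"] == pytest.approx(np.std([1, 3, 5, 7], ddof=1))

    def test_singleton_group_flagged_degenerate(self):
        table = summarize({"solo": [0.7]})
        row = table[table.group == "solo"].iloc[0]
        assert row["std"] == 0.0 and row["degenerate"]

    def test_empty_group_skipped(self):
        with pytest.warns(UserWarning, match="empty"):
            table = summarize({"none": [], "ok": [1.0, 2.0]})
        assert set(table.group) == {"ok", "all"}
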