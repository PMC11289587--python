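import math
from itertools import product

import numpy as np
import pytest
from scipy import stats

from triburst.metrics import (
    binned_percent_change,
    bonferroni_alpha,
    clip_for_display,
    compute_parameters,
    paired_wilcoxon,
)

from conftest import make_spike_set


def signed_rank_exact_p(d):
    """Exhaustive two-sided signed-rank p over all 2^n sign assignments."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_pos = ranks[d > 0].sum()
    total = n * (n + 1) / 2
    w_min, w_max = min(w_pos, total - w_pos), max(w_pos, total - w_pos)
    count = 0
    for signs in product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w <= w_min or w >= w_max:
            count += 1
    return count / 2**n


class TestComputeParameters:
    def _two_burst_set(self, layout):
        # bursts [0,1] with 10 spikes, [2,3] with 20 spikes, 10 spikes outside
        spikes = {
            "A00": np.concatenate(
                [np.linspace(0.05, 0.95, 10), np.linspace(2.05, 2.95, 20), np.linspace(5, 9, 10)]
            )
        }
        return make_spike_set(layout, spikes, 10.0)

    def test_hand_arithmetic_fixture(self, layout):
        s = self._two_burst_set(layout)
        p = compute_parameters([(0, 1), (2, 3)], s, scope="A")
        assert p.mean_ibi == pytest.approx(1.0)
        assert p.mean_burst_duration == pytest.approx(1.0)
        assert p.mean_spike_frequency_in_bursts == pytest.approx(15.0)
        assert p.percent_spikes_in_bursts == pytest.approx(75.0)
        assert p.mean_spikes_in_bursts == pytest.approx(15.0)
        assert p.total_bursts == 2

    def test_unequal_durations_fixture(self, layout):
        # burst [0,2] (8 spikes, 4 Hz) and [10,10.5] (5 spikes, 10 Hz)
        spikes = {"B01": np.concatenate([np.linspace(0.1, 1.9, 8), np.linspace(10.1, 10.4, 5)])}
        s = make_spike_set(layout, spikes, 20.0)
        p = compute_parameters([(0, 2), (10, 10.5)], s, scope="B")
        assert p.mean_ibi == pytest.approx(8.0)
        assert p.mean_burst_duration == pytest.approx(1.25)
        assert p.mean_spike_frequency_in_bursts == pytest.approx((4 + 10) / 2)
        assert p.percent_spikes_in_bursts == pytest.approx(100.0)
        assert p.mean_spikes_in_bursts == pytest.approx(6.5)

    def test_channel_statistics_fixture(self, layout):
        spikes = {
            "C00": np.linspace(0.1, 0.9, 10),
            "C01": np.linspace(0.1, 0.9, 10),
            "C02": [0.5],
        }
        s = make_spike_set(layout, spikes, 2.0)
        p = compute_parameters([(0, 1)], s, scope="C", min_contribution_fraction=0.15)
        assert p.mean_channels_in_bursts == pytest.approx(3.0)
        # mean contribution 21/3 = 7, cutoff 1.05 -> C02 (1 spike) below
        assert p.mean_dominating_channels_in_bursts == pytest.approx(2.0)

    def test_platform_scope_pools_all_compartments(self, layout):
        spikes = {
            "A00": np.linspace(0.1, 0.9, 5),
            "B00": np.linspace(0.1, 0.9, 5),
            "C00": np.linspace(0.1, 0.9, 5),
        }
        s = make_spike_set(layout, spikes, 2.0)
        p = compute_parameters([(0, 1)], s, scope=None)
        assert p.mean_channels_in_bursts == pytest.approx(3.0)
        assert p.mean_spikes_in_bursts == pytest.approx(15.0)

    def test_single_burst_ibi_undefined(self, layout):
        spikes = {"A00": np.linspace(0.1, 0.9, 5)}
        s = make_spike_set(layout, spikes, 2.0)
        p = compute_parameters([(0, 1)], s, scope="A")
        assert math.isnan(p.mean_ibi)
        assert p.total_bursts == 1

    def test_empty_burst_list_all_undefined(self, layout):
        spikes = {"A00": [0.5]}
        s = make_spike_set(layout, spikes, 2.0)
        p = compute_parameters([], s, scope="A")
        assert p.total_bursts == 0
        assert math.isnan(p.mean_burst_duration)
        assert math.isnan(p.percent_spikes_in_bursts)

    def test_percent_invariant_under_time_translation(self, layout):
        rng = np.random.default_rng(0)
        base = np.sort(rng.uniform(0, 10, 200))
        for shift in (0.0, 3.7):
            spikes = {"A05": base + shift}
            s = make_spike_set(layout, spikes, 20.0)
            p = compute_parameters([(2 + shift, 4 + shift), (6 + shift, 7 + shift)], s, scope="A")
            if shift == 0.0:
                ref = p.percent_spikes_in_bursts
        assert p.percent_spikes_in_bursts == pytest.approx(ref)


class TestWilcoxon:
    def test_identical_pairs_p_one(self):
        with pytest.warns(UserWarning):
            assert paired_wilcoxon([1, 2, 3], [1, 2, 3]) == 1.0

    def test_eleven_consistent_increases(self):
        before = np.arange(11, dtype=float)
        after = before + np.linspace(1, 2, 11)  # distinct ranks, all positive
        assert paired_wilcoxon(before, after) == pytest.approx(2 / 2**11)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exact_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        before = rng.normal(0, 1, n)
        after = before + rng.normal(0.3, 1, n)
        assert paired_wilcoxon(before, after) == pytest.approx(
            signed_rank_exact_p(after - before), abs=1e-12
        )

    def test_nan_pairs_dropped(self):
        before = [1.0, 2.0, np.nan, 4.0, 5.0, 6.0]
        after = [2.0, 3.0, 5.0, 5.0, 7.0, 8.0]
        p = paired_wilcoxon(before, after)
        assert 0 < p <= 1


class TestBonferroni:
    @pytest.mark.parametrize("alpha,m,expected", [(0.05, 8, 0.00625), (0.05, 1, 0.05), (0.10, 4, 0.025)])
    def test_adjusted_level(self, alpha, m, expected):
        assert bonferroni_alpha(alpha, m) == pytest.approx(expected)


class TestBinnedPercentChange:
    def _paramset(self, layout, value):
        spikes = {"A00": np.linspace(0.1, 0.9, value)}
        s = make_spike_set(layout, spikes, 2.0)
        return compute_parameters([(0, 1)], s, scope="A")

    def test_equal_to_reference_is_zero(self, layout):
        ref = self._paramset(layout, 10)
        table = binned_percent_change([ref], [ref])
        assert table["bin_1"]["mean_spikes_in_bursts"] == pytest.approx(0.0)

    def test_doubling_and_clipping(self, layout):
        ref = self._paramset(layout, 10)
        double = self._paramset(layout, 20)
        table = binned_percent_change([ref], [double])
        assert table["bin_1"]["mean_spikes_in_bursts"] == pytest.approx(100.0)
        clipped = clip_for_display(table)
        assert clipped["bin_1"]["mean_spikes_in_bursts"] == pytest.approx(50.0)

    def test_decrease(self, layout):
        ref = self._paramset(layout, 10)
        lower = self._paramset(layout, 7)
        table = binned_percent_change([ref], [lower])
        assert table["bin_1"]["mean_spikes_in_bursts"] == pytest.approx(-30.0)

    def test_undefined_reference_marks_nan(self, layout):
        spikes = {"A00": [0.5]}
        s = make_spike_set(layout, spikes, 2.0)
        empty_ref = compute_parameters([], s, scope="A")
        some = self._paramset(layout, 10)
        table = binned_percent_change([empty_ref], [some])
        assert math.isnan(table["bin_1"]["mean_burst_duration"])
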