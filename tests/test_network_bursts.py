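import numpy as np
import pytest

from triburst.bursts import (
    NBDetectionParams,
    apply_channel_criteria,
    detect_nb_initial,
    detect_network_bursts,
    isi_n_threshold,
    isi_n_values,
    merge_adjacent,
    pool_compartment_spikes,
    remove_short,
)
from triburst.synthetic import SimulationParams, gen_spike_lists

from conftest import make_spike_set


class TestPooling:
    def test_merge_sorted(self, layout):
        s = make_spike_set(layout, {"A00": [0.1], "A01": [0.05, 0.2]}, 1.0)
        np.testing.assert_allclose(pool_compartment_spikes(s, "A"), [0.05, 0.1, 0.2])

    def test_empty_compartment(self, layout):
        s = make_spike_set(layout, {}, 1.0)
        assert pool_compartment_spikes(s, "B").size == 0

    def test_count_conservation(self, layout):
        rng = np.random.default_rng(0)
        spikes = {lab: np.unique(rng.uniform(0, 10, 50)) for lab in layout.labels("C")}
        s = make_spike_set(layout, spikes, 10.0)
        assert pool_compartment_spikes(s, "C").size == sum(len(v) for v in spikes.values())


class TestIsiN:
    @pytest.mark.parametrize(
        "train,N,expected",
        [
            ([0, 1, 2, 3], 2, [1, 1, 1]),
            ([0, 1, 2, 3], 4, [3]),
            ([0, 1, 2, 3], 5, []),
        ],
    )
    def test_span_examples(self, train, N, expected):
        np.testing.assert_allclose(isi_n_values(np.array(train, dtype=float), N), expected)

    def test_uniform_10hz_train(self):
        train = np.arange(0, 30, 0.1)
        vals = isi_n_values(train, 20)
        np.testing.assert_allclose(vals, 1.9)


class TestThreshold:
    def test_bimodal_valley_between_modes(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate(
            [rng.lognormal(np.log(0.1), 0.15, 3000), rng.lognormal(np.log(10.0), 0.15, 3000)]
        )
        thr = isi_n_threshold(vals, NBDetectionParams())
        assert 0.3 <= thr <= 3.0

    def test_unimodal_returns_none(self):
        rng = np.random.default_rng(2)
        train = np.cumsum(rng.exponential(0.1, 3000))
        vals = isi_n_values(train, 20)
        assert isi_n_threshold(vals, NBDetectionParams()) is None

    def test_multiplicative_shift_scales_threshold(self):
        rng = np.random.default_rng(3)
        vals = np.concatenate(
            [rng.lognormal(np.log(0.1), 0.15, 3000), rng.lognormal(np.log(10.0), 0.15, 3000)]
        )
        p = NBDetectionParams()
        t1 = isi_n_threshold(vals, p)
        t5 = isi_n_threshold(5.0 * vals, p)
        assert t5 == pytest.approx(5.0 * t1, rel=0.05)


class TestInitialDetection:
    def test_two_dense_runs(self):
        train = np.array([0, 0.01, 0.02, 0.03, 0.04, 5, 5.01, 5.02, 5.03, 5.04])
        bursts = detect_nb_initial(train, 5, 0.1)
        assert bursts == [(0.0, 0.04), (5.0, 5.04)]

    def test_threshold_below_all_spans(self):
        train = np.arange(0, 10, 0.5)
        assert detect_nb_initial(train, 5, 0.001) == []

    def test_single_dense_run(self):
        train = np.arange(0, 1, 0.01)
        bursts = detect_nb_initial(train, 20, 0.5)
        assert len(bursts) == 1
        assert bursts[0] == (0.0, pytest.approx(0.99))


class TestMerging:
    def test_gap_below_fraction_merges(self):
        assert merge_adjacent([(0, 1.0), (1.1, 1.5)], 0.2) == [(0, 1.5)]

    def test_gap_at_fraction_does_not_merge(self):
        assert merge_adjacent([(0, 1.0), (1.3, 1.5)], 0.2) == [(0, 1.0), (1.3, 1.5)]

    def test_zero_fraction_is_identity(self):
        bursts = [(0, 1.0), (1.001, 1.5), (2, 3)]
        assert merge_adjacent(bursts, 0.0) == bursts

    def test_idempotent_and_coverage_nondecreasing(self):
        rng = np.random.default_rng(4)
        t = 0.0
        bursts = []
        for _ in range(50):
            d = rng.uniform(0.05, 2.0)
            bursts.append((t, t + d))
            t += d + rng.uniform(0.01, 1.0)
        merged = merge_adjacent(bursts, 0.2)
        assert merge_adjacent(merged, 0.2) == merged
        assert sum(e - s for s, e in merged) >= sum(e - s for s, e in bursts) - 1e-12
        assert all(merged[i][1] < merged[i + 1][0] for i in range(len(merged) - 1))


class TestRemoveShort:
    def test_drops_below_threshold(self):
        assert remove_short([(0, 0.05), (1, 3.0)], 0.1) == [(1, 3.0)]

    @pytest.mark.parametrize("min_duration", [None, 0])
    def test_disabled_is_identity(self, min_duration):
        bursts = [(0, 0.01), (1, 1.5)]
        assert remove_short(bursts, min_duration) == bursts


class TestChannelCriteria:
    def _spike_set(self, layout, counts):
        # place `counts[i]` spikes for electrode A0i inside [0, 1]
        spikes = {}
        for i, c in enumerate(counts):
            spikes[f"A{i:02d}"] = np.linspace(0.1, 0.9, c) if c else []
        return make_spike_set(layout, spikes, 2.0)

    def test_kept_burst_hand_oracle(self, layout):
        # counts (10, 10, 10, 1): mean 31/4 = 7.75, cutoff 1.1625 -> 3 dominating
        s = self._spike_set(layout, [10, 10, 10, 1])
        out = apply_channel_criteria([(0.0, 1.0)], s, "A", NBDetectionParams())
        assert len(out) == 1
        nb = out[0]
        assert nb.spike_count == 31
        assert len(nb.participating_channels) == 4
        assert nb.dominating_channels == {"A00", "A01", "A02"}

    def test_rejected_burst_hand_oracle(self, layout):
        # counts (30, 1, 1): mean 32/3 = 10.667, cutoff 1.6 -> only 1 dominating
        s = self._spike_set(layout, [30, 1, 1])
        out = apply_channel_criteria([(0.0, 1.0)], s, "A", NBDetectionParams())
        assert out == []

    def test_zero_fraction_dominating_equals_participating(self, layout):
        s = self._spike_set(layout, [5, 2, 1, 1, 7])
        p = NBDetectionParams(min_contribution_fraction=0.0)
        (nb,) = apply_channel_criteria([(0.0, 1.0)], s, "A", p)
        assert nb.dominating_channels == nb.participating_channels

    def test_raising_fraction_never_adds_dominators(self, layout):
        s = self._spike_set(layout, [12, 8, 5, 3, 2, 1])
        sizes = []
        for frac in (0.0, 0.1, 0.3, 0.6, 1.0):
            p = NBDetectionParams(min_contribution_fraction=frac, min_channels=1)
            out = apply_channel_criteria([(0.0, 1.0)], s, "A", p)
            sizes.append(len(out[0].dominating_channels) if out else 0)
        assert sizes == sorted(sizes, reverse=True)


class TestPipelineProperties:
    def test_detected_bursts_disjoint_ordered_and_counted_once(self):
        spikes, _ = gen_spike_lists(SimulationParams(duration=300, nb_count=15, seed=5))
        nbs = detect_network_bursts(spikes, "A")
        assert nbs, "synthetic bursting compartment must yield NBs"
        for a, b in zip(nbs, nbs[1:]):
            assert a.end < b.start
        for nb in nbs:
            assert nb.spike_count == sum(nb.per_channel_counts.values())
            assert nb.dominating_channels <= nb.participating_channels

    def test_planted_bursts_recovered(self):
        spikes, truth = gen_spike_lists(SimulationParams(duration=600, nb_count=30, seed=6))
        nbs = detect_network_bursts(spikes, "B")
        true = truth.compartment_intervals("B")
        hits = sum(
            any(min(e, nb.end) > max(s, nb.start) for nb in nbs) for s, e in true
        )
        false = sum(
            not any(min(e, nb.end) > max(s, nb.start) for s, e in true) for nb in nbs
        )
        assert hits == len(true)
        assert false == 0

    def test_sparse_compartment_yields_no_bursts(self, layout):
        rng = np.random.default_rng(7)
        spikes = {lab: np.unique(rng.uniform(0, 60, 10)) for lab in layout.labels("A")}
        s = make_spike_set(layout, spikes, 60.0)
        assert detect_network_bursts(s, "A") == []
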