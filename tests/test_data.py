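import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from popwarp.data import (SpikeDataset, bin_spikes, gaussian_smooth,
                          population_train, psth, rank_conditions_by_tv,
                          select_active_neurons, total_variation)


def make_dataset(rows):
    df = pd.DataFrame(rows, columns=["neuron_id", "area", "condition_id",
                                     "trial_id", "time_ms"])
    return SpikeDataset(spikes=df, window=(0.0, 500.0))


class TestBinSpikes:
    @pytest.mark.parametrize("times,window,dt,expected", [
        ([1.0, 3.5, 3.9], (0, 4), 2.0, [1, 2]),
        ([], (0, 10), 2.0, [0, 0, 0, 0, 0]),
        ([4.0], (0, 4), 2.0, [0, 0]),          # spike at exactly T dropped
        ([0.0, 1.999, 2.0], (0, 4), 2.0, [2, 1]),  # half-open bins
    ])
    def test_examples(self, times, window, dt, expected):
        assert bin_spikes(times, window, dt).counts.tolist() == expected

    def test_conservation_oracle(self, rng):
        times = rng.uniform(0, 500, size=1000)
        assert bin_spikes(times, (0, 500), 2.0).total == 1000

    def test_rejects_out_of_window(self):
        with pytest.raises(ValueError):
            bin_spikes([-1.0], (0, 500), 2.0)
        with pytest.raises(ValueError):
            bin_spikes([501.0], (0, 500), 2.0)

    def test_rejects_nondivisible_width(self):
        with pytest.raises(ValueError):
            bin_spikes([1.0], (0, 500), 3.0)

    @given(st.lists(st.floats(min_value=0, max_value=499.99), max_size=40))
    def test_count_conserved_property(self, times):
        assert bin_spikes(times, (0, 500), 2.0).total == len(times)


class TestPopulationTrain:
    def test_additivity_and_identity(self):
        ds = make_dataset([(1, "V1", 0, 0, 1.0), (2, "V1", 0, 0, 2.5),
                           (2, "V1", 0, 0, 3.0)])
        merged = population_train(ds, [1, 2], 0, 0)
        n1 = population_train(ds, [1], 0, 0)
        n2 = population_train(ds, [2], 0, 0)
        assert np.array_equal(merged.counts, n1.counts + n2.counts)
        assert n1.total == 1 and n2.total == 2

    def test_merge_order_oracle(self, rng):
        """Merging spike times then binning equals summing binned trains."""
        rows = []
        for n in range(5):
            for t in rng.uniform(0, 500, size=20):
                rows.append((n, "V1", 0, 0, t))
        ds = make_dataset(rows)
        merged = population_train(ds, list(range(5)), 0, 0)
        summed = sum(population_train(ds, [n], 0, 0).counts for n in range(5))
        assert np.array_equal(merged.counts, summed)

    def test_empty_member_set_rejected(self):
        ds = make_dataset([(1, "V1", 0, 0, 1.0)])
        with pytest.raises(ValueError, match="degenerate"):
            population_train(ds, [], 0, 0)

    def test_cross_area_rejected(self):
        ds = make_dataset([(1, "V1", 0, 0, 1.0), (2, "LM", 0, 0, 2.0)])
        with pytest.raises(ValueError, match="single area"):
            population_train(ds, [1, 2], 0, 0)


class TestPSTH:
    def test_unit_conversion(self):
        ds = make_dataset([(1, "V1", 0, 0, 0.5)])
        rate = psth(ds, [1], 0)
        assert rate[0] == pytest.approx(500.0)  # 1 spike / (1 neuron * 2 ms)
        assert rate[1:].sum() == 0

    def test_linearity_over_trials(self, rng):
        rows = []
        for r in (0, 1):
            for t in rng.uniform(0, 500, 30):
                rows.append((1, "V1", 0, r, t))
                rows.append((1, "V1", 1, r, t))   # doubled in condition 1
                rows.append((1, "V1", 1, r, min(t + 0.1, 499.9)))
        ds = make_dataset(rows)
        assert psth(ds, [1], 1).sum() == pytest.approx(2 * psth(ds, [1], 0).sum())

    def test_poisson_rate_oracle(self, rng):
        """Homogeneous Poisson at 20 Hz: PSTH within 3 SEs of 20 per bin."""
        n_trials, rate_hz, dt = 200, 20.0, 2.0
        rows = []
        for r in range(n_trials):
            n = rng.poisson(rate_hz * 0.5)
            for t in rng.uniform(0, 500, n):
                rows.append((1, "V1", 0, r, t))
        ds = make_dataset(rows)
        est = psth(ds, [1], 0)
        se = np.sqrt(rate_hz / (n_trials * dt / 1000.0))
        assert np.all(np.abs(est - rate_hz) < 3.5 * se)


class TestSelectActiveNeurons:
    def test_ranking_and_tie_rule(self):
        rows = []
        for n, k in [(1, 10), (2, 5), (3, 8), (4, 1)]:
            rows += [(n, "V1", 0, 0, float(i) + 1) for i in range(k)]
        ds = make_dataset(rows)
        assert select_active_neurons(ds, 0.5) == [1, 3]

    def test_all_equal_counts_takes_lowest_ids(self):
        rows = [(n, "V1", 0, 0, float(n)) for n in [5, 2, 9, 7]]
        ds = make_dataset(rows)
        assert select_active_neurons(ds, 0.5) == [2, 5]

    def test_matches_sort_and_slice_oracle(self, rng):
        counts = {n: int(k) for n, k in enumerate(rng.integers(0, 30, size=11))}
        rows = []
        for n, k in counts.items():
            rows += [(n, "V1", 0, 0, float(i) + 0.5) for i in range(k)]
            if k == 0:
                rows.append((n, "V1", 0, 0, 0.25))
                counts[n] = 1
        ds = make_dataset(rows)
        expect = sorted(sorted(counts, key=lambda n: (-counts[n], n))[:6])
        assert select_active_neurons(ds, 0.5) == expect

    def test_idempotent(self, rng):
        rows = [(n, "V1", 0, 0, float(t)) for n in range(8)
                for t in rng.uniform(0, 500, rng.integers(1, 20))]
        ds = make_dataset(rows)
        first = select_active_neurons(ds, 0.5)
        sub = ds.spikes[ds.spikes.neuron_id.isin(first)]
        ds2 = SpikeDataset(spikes=sub.reset_index(drop=True), window=(0, 500))
        assert select_active_neurons(ds2, 1.0) == first


class TestConditionRanking:
    def test_total_variation_examples(self):
        assert total_variation([5, 5, 5, 5]) == 0.0
        assert total_variation([0, 1, 0.5, 2]) == pytest.approx(3.0)

    def test_smoothing_preserves_constant(self):
        out = gaussian_smooth(np.full(50, 7.0), sd_bins=5.0)
        assert np.allclose(out, 7.0)

    def test_scores_additive_over_areas(self, rng):
        rows = []
        for a in ("V1", "LM"):
            base = 1000 if a == "LM" else 0
            for t in rng.uniform(0, 500, 50):
                rows.append((base + 1, a, 0, 0, t))
        ds = make_dataset(rows)
        both = rank_conditions_by_tv(ds, areas=["V1", "LM"])
        v1 = rank_conditions_by_tv(ds, areas=["V1"])
        lm = rank_conditions_by_tv(ds, areas=["LM"])
        assert both.tv_score[0] == pytest.approx(v1.tv_score[0] + lm.tv_score[0])

    def test_fluctuating_condition_ranks_first(self, rng):
        rows = []
        # condition 0: strong burst; condition 1: flat
        for r in range(5):
            for t in rng.normal(100, 5, 40):
                rows.append((1, "V1", 0, r, float(np.clip(t, 0, 499))))
            for t in rng.uniform(0, 500, 40):
                rows.append((1, "V1", 1, r, t))
        ds = make_dataset(rows)
        ranked = rank_conditions_by_tv(ds)
        assert ranked.condition_id[0] == 0


class TestSpikeDatasetIO:
    def test_table_round_trip(self, tmp_path, rng):
        rows = [(n, a, c, r, float(t))
                for n, a in [(1, "V1"), (2, "LM")]
                for c in (0, 1) for r in (0, 1)
                for t in rng.uniform(0, 500, 3)]
        ds = make_dataset(rows)
        path = tmp_path / "spikes.tsv"
        ds.to_table(path)
        back = SpikeDataset.from_table(path)
        pd.testing.assert_frame_equal(
            back.spikes.sort_values(["neuron_id", "time_ms"]).reset_index(drop=True),
            ds.spikes.sort_values(["neuron_id", "time_ms"]).reset_index(drop=True))

    def test_neuron_in_two_areas_rejected(self):
        with pytest.raises(ValueError):
            make_dataset([(1, "V1", 0, 0, 1.0), (1, "LM", 0, 0, 2.0)])
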