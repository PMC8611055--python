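import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vnseeg import (
    SynthConfig,
    cbpt,
    cbpt_2d_baseline,
    critical_value,
    form_clusters,
    generate_trial_tensor,
    group_factorial,
    pointwise_anova,
)

from tests.oracles import (
    anova_2x2_cell_means,
    brute_force_cbpt_two_sample,
    brute_force_clusters,
)


class TestPointwiseAnova:
    def test_no_effect_on_equal_cell_means(self):
        values = np.array([1.0, 2.0, 1.0, 2.0, 1.0, 2.0, 1.0, 2.0])
        freq = ["low"] * 4 + ["high"] * 4
        amp = ["low", "low", "high", "high"] * 2
        tr = pointwise_anova(values, (freq, amp))
        assert tr.F_frequency[0] < 1e-9
        assert tr.F_amplitude[0] < 1e-9
        assert tr.F_interaction[0] < 1e-9

    def test_hand_computed_2x2(self):
        """Cells {10-low: (1,2), 10-high: (1,2), 30-low: (3,4),
        30-high: (3,4)} give F_freq = 16, F_amp = 0, F_int = 0 on df (1,4),
        verified against the classical cell-means decomposition."""
        values = np.array([1.0, 2.0, 1.0, 2.0, 3.0, 4.0, 3.0, 4.0])
        freq = ["10", "10", "10", "10", "30", "30", "30", "30"]
        amp = ["low", "low", "high", "high"] * 2
        tr = pointwise_anova(values, (freq, amp))
        f_f, f_a, f_i, df_e = anova_2x2_cell_means(values, freq, amp)
        assert tr.F_frequency[0] == pytest.approx(f_f)
        assert tr.F_amplitude[0] == pytest.approx(f_a)
        assert tr.F_interaction[0] == pytest.approx(f_i)
        assert tr.F_frequency[0] == pytest.approx(16.0)
        assert tr.df_error[0] == 4

    def test_matches_cell_means_oracle_on_random_balanced_data(self):
        rng = np.random.default_rng(0)
        freq = np.repeat(["low", "high"], 20)
        amp = np.tile(np.repeat(["low", "high"], 10), 2)
        values = rng.standard_normal((50, 40))
        tr = pointwise_anova(values, (freq, amp))
        for t in range(0, 50, 7):
            f_f, f_a, f_i, _ = anova_2x2_cell_means(values[t], freq, amp)
            assert tr.F_frequency[t] == pytest.approx(f_f)
            assert tr.F_amplitude[t] == pytest.approx(f_a)
            assert tr.F_interaction[t] == pytest.approx(f_i)

    def test_nan_trials_dropped_with_df_recomputed(self):
        rng = np.random.default_rng(1)
        freq = np.repeat(["low", "high"], 10)
        amp = np.tile(np.repeat(["low", "high"], 5), 2)
        values = rng.standard_normal((3, 20))
        values[1, 0] = np.nan
        tr = pointwise_anova(values, (freq, amp))
        assert tr.df_error[0] == 16
        assert tr.df_error[1] == 15
        sub = pointwise_anova(values[1, 1:], (freq[1:], amp[1:]))
        assert tr.F_frequency[1] == pytest.approx(sub.F_frequency[0])

    def test_empty_cell_rejected(self):
        freq = ["low"] * 4 + ["high"] * 2
        amp = ["low", "low", "high", "high", "low", "low"]
        with pytest.raises(ValueError, match="cell"):
            pointwise_anova(np.zeros(6), (freq, amp))


class TestCriticalValue:
    def test_f_quantile(self):
        assert critical_value(0.05, (1, 116), "F") == pytest.approx(3.923, abs=1e-3)

    def test_two_sided_normal(self):
        assert critical_value(0.05, np.inf, "t") == pytest.approx(1.960, abs=1e-3)
        assert critical_value(0.05, None, "z") == pytest.approx(1.960, abs=1e-3)

    def test_monotone_in_alpha(self):
        thresholds = [critical_value(a, (1, 30), "F") for a in (0.2, 0.05, 0.01, 0.001)]
        assert np.all(np.diff(thresholds) > 0)

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            critical_value(0.05, (0, 10), "F")


class TestFormClusters:
    def test_enumerated_example(self):
        trace = np.array([0.1, 5.0, 6.0, 0.2, 7.0])
        clusters = form_clusters(trace, 4.0)
        sums = sorted(c.cluster_sum for c in clusters)
        assert sums == [7.0, 11.0]
        big = max(clusters, key=lambda c: c.cluster_sum)
        assert list(np.flatnonzero(big.mask)) == [1, 2]

    def test_matches_brute_force_on_random_traces(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            trace = rng.standard_normal(50) * 3
            got = form_clusters(trace, 2.0)
            ref = brute_force_clusters(trace, 2.0)
            assert sorted(round(c.cluster_sum, 9) for c in got) == sorted(
                round(s, 9) for _, s in ref
            )

    def test_all_subthreshold_empty(self):
        assert form_clusters(np.zeros(10), 1.0) == []

    def test_nan_is_subthreshold(self):
        trace = np.array([5.0, np.nan, 5.0])
        clusters = form_clusters(trace, 4.0)
        assert len(clusters) == 2

    def test_diagonal_cells_not_connected_in_2d(self):
        grid = np.zeros((3, 3))
        grid[0, 0] = grid[1, 1] = 5.0
        clusters = form_clusters(grid, 4.0, adjacency="2d")
        assert len(clusters) == 2

    def test_signed_clusters_formed_separately(self):
        trace = np.array([3.0, -3.0, 3.0])
        clusters = form_clusters(trace, 2.0, signed=True)
        sums = sorted(c.cluster_sum for c in clusters)
        assert sums == [-3.0, 3.0, 3.0]

    def test_raising_threshold_never_grows_clusters(self):
        rng = np.random.default_rng(3)
        trace = rng.standard_normal(200) * 2
        low = form_clusters(trace, 1.0)
        high = form_clusters(trace, 2.0)
        max_extent_low = max(c.mask.sum() for c in low)
        max_extent_high = max((c.mask.sum() for c in high), default=0)
        assert max_extent_high <= max_extent_low


class TestCbpt:
    def test_matches_brute_force_exactly(self):
        """On a small trace the vectorized CBPT reproduces an explicit-loop
        implementation: same cluster sums and identical permutation
        p-values under a shared seed."""
        rng = np.random.default_rng(4)
        data = rng.standard_normal((30, 8))
        data[10:20, 4:] += 1.5
        groups = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        ref, thr = brute_force_cbpt_two_sample(data, groups, 300, 0.05, seed=99)
        got = cbpt(data, groups, statistic="two_sample_t",
                   n_permutations=300, seed=99)
        assert got.critical_value == pytest.approx(thr)
        ref_sums = sorted(round(s, 9) for _, s, _ in ref)
        got_sums = sorted(round(c.cluster_sum, 9) for c in got.clusters)
        assert got_sums == ref_sums
        ref_by_sum = {round(s, 9): p for _, s, p in ref}
        for c in got.clusters:
            assert c.p_value == pytest.approx(ref_by_sum[round(c.cluster_sum, 9)])

    def test_boundary_p_value_is_one_over_nplus1(self):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((100, 40)) * 0.1
        data[40:60, 20:] += 5.0  # overwhelming effect
        groups = np.repeat([0, 1], 20)
        res = cbpt(data, groups, statistic="two_sample_t",
                   n_permutations=1000, seed=6)
        assert min(c.p_value for c in res.clusters) == pytest.approx(1 / 1001)

    def test_trial_reordering_leaves_result_unchanged(self):
        rng = np.random.default_rng(7)
        data = rng.standard_normal((50, 20))
        groups = np.repeat([0, 1], 10)
        perm = rng.permutation(20)
        a = cbpt(data, groups, statistic="two_sample_t",
                 n_permutations=200, seed=8)
        b = cbpt(data[:, perm], groups[perm], statistic="two_sample_t",
                 n_permutations=200, seed=8)
        assert sorted(round(c.cluster_sum, 9) for c in a.clusters) == sorted(
            round(c.cluster_sum, 9) for c in b.clusters
        )

    def test_anova_statistic_finds_planted_frequency_effect(self, effect_tensor):
        tensor, truth = effect_tensor
        res = cbpt(tensor.z[0], tensor.condition, statistic="anova_frequency",
                   n_permutations=500, seed=9)
        sig = res.significant(0.05)
        assert sig
        t = tensor.time_axis
        best = max(sig, key=lambda c: c.cluster_sum)
        idx = np.flatnonzero(best.mask)
        assert t[idx[0]] < 6.0 and t[idx[-1]] > 2.0

    def test_rank_sum_statistic_runs_and_detects(self, effect_tensor):
        tensor, _ = effect_tensor
        hi = tensor.condition_trials("high", "high")
        lo = tensor.condition_trials("low", "high")
        data = tensor.z[0][:, np.concatenate([hi, lo])]
        groups = np.repeat([1, 0], [len(hi), len(lo)])
        res = cbpt(data, groups, statistic="rank_sum",
                   n_permutations=300, seed=10)
        assert res.significant(0.05)

    def test_statistic_label_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cbpt(np.zeros((10, 6)), np.array([0, 1, 2, 0, 1, 2]),
                 statistic="two_sample_t", n_permutations=100, seed=0)

    def test_few_permutations_warns(self):
        rng = np.random.default_rng(11)
        with pytest.warns(UserWarning, match="permutations"):
            cbpt(rng.standard_normal((10, 8)), np.repeat([0, 1], 4),
                 statistic="two_sample_t", n_permutations=50, seed=0)


class TestCbpt2d:
    def _trials(self, seed, shift=0.0):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((12, 80, 30))
        if shift:
            x[2:8, 20:60, :] += shift
        return x

    def test_planted_region_recovered(self):
        x = self._trials(0, shift=0.6)
        res = cbpt_2d_baseline(x, n_permutations=300, seed=1)
        sig = res.significant(0.05)
        assert sig
        best = max(sig, key=lambda c: abs(c.cluster_sum))
        planted = np.zeros((12, 80), dtype=bool)
        planted[2:8, 20:60] = True
        overlap = (best.mask & planted).sum() / planted.sum()
        assert overlap >= 0.5
        assert best.extra["mean_z"] == pytest.approx(0.6, abs=0.15)

    def test_pure_noise_rarely_significant(self):
        hits = 0
        for seed in range(10):
            res = cbpt_2d_baseline(self._trials(100 + seed), n_permutations=200,
                                   seed=seed)
            if res.significant(0.05):
                hits += 1
        assert hits <= 2

    def test_sign_flip_symmetry(self):
        x = self._trials(3, shift=0.5)
        a = cbpt_2d_baseline(x, n_permutations=100, seed=4)
        b = cbpt_2d_baseline(-x, n_permutations=100, seed=4)
        sums_a = sorted(round(c.cluster_sum, 6) for c in a.clusters)
        sums_b = sorted(round(-c.cluster_sum, 6) for c in b.clusters)
        assert sums_a == sums_b

    def test_cluster_extent_reporting(self):
        x = self._trials(5, shift=0.8)
        bands = np.linspace(1, 20, 12)
        taxis = np.linspace(-4, 11, 80)
        res = cbpt_2d_baseline(x, n_permutations=100, seed=6,
                               band_centers=bands, time_axis=taxis)
        best = max(res.significant(0.05), key=lambda c: abs(c.cluster_sum))
        lo, hi = best.extra["band_range_hz"]
        assert lo <= bands[2] and hi >= bands[7]


class TestGroupFactorial:
    def _window_table(self, seed, interaction=0.0):
        rng = np.random.default_rng(seed)
        rows = []
        for modality in ("iVNS", "taVNS-matched"):
            for band in ("delta", "theta"):
                for f_lvl in ("low", "high"):
                    for a_lvl in ("low", "high"):
                        mean = 0.0
                        if interaction and modality == "iVNS" and f_lvl == "high":
                            mean = interaction
                        for _ in range(20):
                            rows.append(
                                {"mean_z": rng.normal(mean, 1.0),
                                 "frequency_level": f_lvl,
                                 "amplitude_level": a_lvl,
                                 "modality": modality, "band": band}
                            )
        return pd.DataFrame(rows)

    def test_planted_frequency_modality_interaction_dominates(self):
        hits = 0
        for seed in range(10):
            table = group_factorial(self._window_table(seed, interaction=0.8))
            inter = table[table.index.str.count(":") == 1]
            fm = [i for i in inter.index
                  if "frequency_level" in i and "modality" in i][0]
            if inter.loc[fm, "F"] == inter.F.max():
                hits += 1
        assert hits >= 9

    def test_null_p_values_roughly_uniform(self):
        ps = []
        for seed in range(20):
            table = group_factorial(self._window_table(100 + seed))
            ps.extend(table.p.tolist())
        ps = np.array(ps)
        assert 0.25 < np.mean(ps < 0.5) < 0.75
        assert np.mean(ps < 0.05) < 0.2

    def test_single_modality_matches_pointwise_anova_on_window_means(self):
        """Restricted to one modality and band, the group model's frequency
        and amplitude F match a 2 x 2 ANOVA of the same window means."""
        rng = np.random.default_rng(42)
        freq = np.repeat(["low", "high"], 30)
        amp = np.tile(np.repeat(["low", "high"], 15), 2)
        y = rng.standard_normal(60) + (freq == "high") * 0.5
        df = pd.DataFrame({"mean_z": y, "frequency_level": freq,
                           "amplitude_level": amp})
        table = group_factorial(df)
        tr = pointwise_anova(y, (freq, amp))
        f_row = [i for i in table.index
                 if "frequency" in i and ":" not in i][0]
        assert table.loc[f_row, "F"] == pytest.approx(tr.F_frequency[0])

    def test_bonferroni_level_recorded(self):
        table = group_factorial(self._window_table(0))
        assert table.attrs["bonferroni_alpha"] == 0.003

    def test_single_level_factors_dropped(self):
        df = self._window_table(1)
        df = df[df.modality == "iVNS"]
        table = group_factorial(df)
        assert not any("modality" in i for i in table.index)
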