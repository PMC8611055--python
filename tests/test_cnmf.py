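import numpy as np
import pytest

from vnseeg import (
    SynthConfig,
    adjusted_rand_index,
    cnmf_fit,
    condition_average_concat,
    generate_trial_tensor,
    impute_nan_linear,
    impute_tensor,
    project_weights,
    select_rank,
)

from tests.oracles import rand_index_adjusted


def block_matrix(n_per_block=4, n_t=200, seed=0, noise=0.0):
    """Two exactly orthogonal block timecourses over disjoint electrodes."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_t) / 100.0
    c1 = np.abs(np.sin(2 * np.pi * 1.0 * t)) + 0.5
    c2 = np.zeros(n_t)
    c2[: n_t // 2] = 2.0
    X = np.zeros((n_t, 2 * n_per_block))
    X[:, :n_per_block] = c1[:, None]
    X[:, n_per_block:] = c2[:, None]
    if noise:
        X += rng.normal(0, noise, X.shape)
    truth = np.repeat([1, 2], n_per_block)
    return X, truth


class TestCnmfFit:
    def test_block_structure_recovered(self):
        X, truth = block_matrix(noise=0.02)
        dec = cnmf_fit(X, 2, seed=0)
        ari, agree = adjusted_rand_index(dec.assignments, truth)
        assert ari == 1.0
        rel = dec.reconstruction_error / np.sum(X**2)
        assert rel < 1e-3

    def test_rank1_matrix_fit_exactly(self):
        t = np.linspace(0, 1, 100)
        base = np.exp(-t)
        X = np.outer(base, [1.0, 2.0, 3.0])
        dec = cnmf_fit(X, 2, seed=1)
        assert dec.reconstruction_error < 1e-6 * np.sum(X**2)

    def test_same_seed_identical_decomposition(self):
        X, _ = block_matrix(noise=0.2, seed=3)
        a = cnmf_fit(X, 2, seed=7)
        b = cnmf_fit(X, 2, seed=7)
        assert np.array_equal(a.W, b.W)
        assert np.array_equal(a.G, b.G)
        assert np.array_equal(a.assignments, b.assignments)

    def test_error_trace_non_increasing(self):
        X, _ = block_matrix(noise=0.3, seed=4)
        dec = cnmf_fit(X, 3, seed=2)
        assert np.all(np.diff(dec.error_trace) <= 1e-9)

    def test_factors_nonnegative_and_f_equals_xw(self):
        X, _ = block_matrix(noise=0.2, seed=5)
        dec = cnmf_fit(X, 2, seed=3)
        assert np.all(dec.W >= 0)
        assert np.all(dec.G >= 0)
        assert np.allclose(dec.F, X @ dec.W)
        assert set(dec.assignments) <= {1, 2}

    def test_scaling_x_scales_f_but_not_assignments(self):
        X, _ = block_matrix(noise=0.2, seed=6)
        a = cnmf_fit(X, 2, seed=4)
        b = cnmf_fit(3.0 * X, 2, seed=4)
        assert np.array_equal(a.assignments, b.assignments)
        assert np.allclose(b.F, 3.0 * a.F, rtol=1e-4)

    def test_electrode_permutation_permutes_outputs(self):
        X, _ = block_matrix(noise=0.2, seed=8)
        perm = np.random.default_rng(0).permutation(X.shape[1])
        a = cnmf_fit(X, 2, seed=5)
        b = cnmf_fit(X[:, perm], 2, seed=5)
        # same partition up to electrode relabeling
        ari, _ = adjusted_rand_index(a.assignments[perm], b.assignments)
        assert ari == 1.0

    def test_invalid_inputs_rejected(self):
        X, _ = block_matrix()
        with pytest.raises(ValueError):
            cnmf_fit(X, 1, seed=0)
        with pytest.raises(ValueError):
            cnmf_fit(X, 8, seed=0)
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite|impute"):
            cnmf_fit(X, 2, seed=0)


class TestSelectRank:
    def _planted(self, n_clusters, seed, n_per=5, n_t=300, sep=3.0, noise=0.5):
        rng = np.random.default_rng(seed)
        t = np.arange(n_t)
        X = np.empty((n_t, n_clusters * n_per))
        for k in range(n_clusters):
            proto = np.sin(2 * np.pi * (k + 1) * t / n_t) * sep + sep
            X[:, k * n_per : (k + 1) * n_per] = proto[:, None]
        X += rng.normal(0, noise, X.shape)
        return X, np.repeat(np.arange(n_clusters) + 1, n_per)

    def test_three_planted_clusters_rank3_preferred(self):
        hits = 0
        for seed in range(10):
            X, _ = self._planted(3, seed)
            report = select_rank(X, candidate_ranks=range(2, 6), seed=seed,
                                 n_restarts=5)
            if report.chosen_rank == 3:
                hits += 1
        assert hits >= 8

    def test_two_planted_clusters_rank2_preferred(self):
        hits = 0
        for seed in range(10):
            X, _ = self._planted(2, seed)
            report = select_rank(X, candidate_ranks=range(2, 6), seed=seed,
                                 n_restarts=5)
            if report.chosen_rank == 2:
                hits += 1
        assert hits >= 8

    def test_error_non_increasing_in_rank(self):
        X, _ = self._planted(3, seed=0, noise=1.0)
        report = select_rank(X, candidate_ranks=range(2, 7), seed=1, n_restarts=3)
        errs = [report.decompositions[r].reconstruction_error for r in report.ranks]
        assert np.all(np.diff(errs) <= 1e-9)

    def test_report_structure_and_tie_rule(self):
        X, _ = self._planted(2, seed=2)
        report = select_rank(X, candidate_ranks=range(2, 5), seed=3, n_restarts=3)
        assert report.ranks == [2, 3, 4]
        assert set(report.indices) == {"wemmert_gancarski", "pbm", "wb", "xie_beni"}
        assert report.chosen_rank in report.ranks
        votes = list(report.preferred.values())
        top = max(votes.count(r) for r in set(votes))
        winners = [r for r in set(votes) if votes.count(r) == top]
        assert report.chosen_rank == min(winners)


class TestImputation:
    def test_midpoint(self):
        assert np.allclose(impute_nan_linear(np.array([[1.0, np.nan, 3.0]])),
                           [[1.0, 2.0, 3.0]])

    def test_edge_fill(self):
        assert np.allclose(impute_nan_linear(np.array([[np.nan, 2.0, 4.0]])),
                           [[2.0, 2.0, 4.0]])

    def test_no_nan_identity(self):
        x = np.arange(12.0).reshape(3, 4)
        assert np.array_equal(impute_nan_linear(x), x)

    def test_all_nan_row_rejected(self):
        with pytest.raises(ValueError, match="row"):
            impute_nan_linear(np.array([[1.0, 2.0], [np.nan, np.nan]]))

    def test_tensor_imputation_bridges_across_trials(self):
        z = np.arange(24.0).reshape(2, 3, 4)  # electrodes x time x trials
        z[0, 1, 2] = np.nan
        out = impute_tensor(z)
        assert np.isfinite(out).all()
        # unfolding concatenates trials: the gap is bridged by its own
        # trial's neighbours in time
        assert out[0, 1, 2] == pytest.approx((z[0, 0, 2] + z[0, 2, 2]) / 2)


class TestProjectWeights:
    def test_one_hot_column_selects_electrode(self, effect_tensor):
        tensor, _ = effect_tensor
        W = np.zeros((8, 2))
        W[3, 0] = 1.0
        W[5, 1] = 1.0
        proj = project_weights(W, tensor)
        assert np.allclose(proj[0], tensor.z[3])
        assert np.allclose(proj[1], tensor.z[5])

    def test_uniform_column_is_plain_mean(self, effect_tensor):
        tensor, _ = effect_tensor
        W = np.ones((8, 1))
        proj = project_weights(W, tensor)
        assert np.allclose(proj[0], tensor.z.mean(axis=0))

    def test_projected_clusters_show_planted_separation(self, effect_tensor):
        """End to end on the z-domain generator: cNMF weights projected
        onto trials separate the planted high- vs low-frequency response."""
        tensor, truth = effect_tensor
        cm = condition_average_concat(tensor)
        from vnseeg import cnmf_fit
        dec = cnmf_fit(cm, 2, seed=0)
        ari, _ = adjusted_rand_index(dec.assignments, truth.cluster_assignment)
        assert ari == 1.0
        proj = project_weights(dec.W, tensor)
        w = tensor.window_mask(truth.effect_window)
        hi = tensor.condition_trials("high", "high")
        lo = tensor.condition_trials("low", "high")
        # electrode 0 belongs to planted cluster 1; its hard label names
        # the corresponding component
        sc1 = dec.assignments[0] - 1
        diff = proj[sc1][w][:, hi].mean() - proj[sc1][w][:, lo].mean()
        assert diff == pytest.approx(0.28 + 0.25, abs=0.1)

    def test_shape_mismatch_rejected(self, effect_tensor):
        tensor, _ = effect_tensor
        with pytest.raises(ValueError, match="electrode"):
            project_weights(np.ones((5, 2)), tensor)

    def test_nan_tensor_rejected(self, effect_tensor):
        tensor, _ = effect_tensor
        z = tensor.z.copy()
        z[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="impute"):
            project_weights(np.ones((8, 2)), z)


class TestAdjustedRandIndex:
    def test_identical_partitions(self):
        labels = [1, 1, 2, 3, 3, 3]
        ari, agree = adjusted_rand_index(labels, labels)
        assert ari == 1.0
        assert agree == 100.0

    def test_hand_example_minus_half(self):
        ari, _ = adjusted_rand_index([1, 1, 2, 2], [1, 2, 1, 2])
        assert ari == pytest.approx(-0.5)

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.integers(0, 4, 30)
            b = rng.integers(0, 3, 30)
            ari, _ = adjusted_rand_index(a, b)
            assert ari == pytest.approx(rand_index_adjusted(a, b))

    def test_matches_sklearn_reference(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.integers(0, 5, 50)
            b = rng.integers(0, 4, 50)
            ari, _ = adjusted_rand_index(a, b)
            assert ari == pytest.approx(adjusted_rand_score(a, b))

    def test_symmetric_and_label_invariant(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 3, 40)
        b = rng.integers(0, 3, 40)
        assert adjusted_rand_index(a, b)[0] == pytest.approx(
            adjusted_rand_index(b, a)[0]
        )
        remap = np.array([7, 2, 5])
        assert adjusted_rand_index(remap[a], b)[0] == pytest.approx(
            adjusted_rand_index(a, b)[0]
        )

    def test_chance_level_near_zero(self):
        rng = np.random.default_rng(3)
        vals = [
            adjusted_rand_index(rng.integers(0, 4, 200),
                                rng.integers(0, 4, 200))[0]
            for _ in range(500)
        ]
        assert abs(np.mean(vals)) < 0.02

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            adjusted_rand_index([1, 2], [1, 2, 3])

    def test_percent_agreement_under_optimal_matching(self):
        # labels match after renaming 1<->2: agreement 100% though labels differ
        _, agree = adjusted_rand_index([1, 1, 2, 2], [2, 2, 1, 1])
        assert agree == 100.0
        _, agree2 = adjusted_rand_index([1, 1, 2, 2], [2, 1, 1, 1])
        assert agree2 == 75.0
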