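import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from mrcl import (
    DataMatrix,
    PairFeatureMatrix,
    baseline_correlation,
    baseline_knn,
    build_pair_index,
    gold_standard,
    roc_auc,
    sample_labels_random,
    sample_labels_rowwise,
)
from mrcl.evaluation import passes_rowwise_screen, passes_sparsity_screen
from mrcl.learner import PartialLabels


def make_obs(rng, n=40, p=2, names=None):
    return DataMatrix(rng.normal(size=(n, p)),
                      names or [f"V{i}" for i in range(p)])


class TestGoldStandard:
    def hand_case(self, zeta_target, tau=5.0):
        """Place the interventional measurement exactly zeta_target robust
        z-score units from the observational median."""
        rng = np.random.default_rng(8)
        obs = make_obs(rng, n=30, names=["a", "b"])
        ref = gold_standard(np.zeros((2, 2)), obs, tau=tau, seed=0)
        Z = np.zeros((2, 2))
        Z[0, 1] = ref.obs_medians[1] + zeta_target * ref.obs_iqrs[1]
        return gold_standard(Z, obs, tau=tau, seed=0)

    def test_tie_at_threshold_is_no_edge(self):
        # the edge rule is strict: zeta exactly equal to tau is not an edge
        gs = self.hand_case(5.0)
        assert gs.zeta[0, 1] == pytest.approx(5.0)
        tie = self.hand_case(5.0, tau=float(gs.zeta[0, 1]))
        assert tie.adjacency[0, 1] == 0

    def test_just_above_threshold_is_edge(self):
        gs = self.hand_case(5.1)
        assert gs.zeta[0, 1] == pytest.approx(5.1)
        assert gs.adjacency[0, 1] == 1

    def test_no_change_is_never_an_edge(self):
        gs = self.hand_case(0.0)  # measurement equals the median
        assert gs.zeta[0, 1] == pytest.approx(0.0)
        assert gs.adjacency[0, 1] == 0

    def test_zeta_formula_on_known_half(self):
        # recompute |Z - median| / IQR from the realized split
        rng = np.random.default_rng(4)
        obs = make_obs(rng, n=24, p=3, names=["a", "b", "c"])
        Z = rng.normal(size=(3, 3))
        gs = gold_standard(Z, obs, tau=1.0, seed=2)
        expected = np.abs(Z - gs.obs_medians[None, :]) / gs.obs_iqrs[None, :]
        np.testing.assert_allclose(gs.zeta, expected, rtol=1e-12)

    def test_zero_iqr_errors_with_variable_name(self, rng):
        obs = DataMatrix(np.column_stack([np.r_[np.zeros(9), 1.0],
                                          rng.normal(size=10)]),
                         ["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            gold_standard(np.zeros((2, 2)), obs, seed=1)

    def test_training_half_is_the_complement(self, rng):
        obs = make_obs(rng, n=41)
        gs = gold_standard(np.zeros((2, 2)), obs, tau=1.0, seed=5)
        assert gs.training_data.n == 41 - 41 // 2
        # reproducible split
        gs2 = gold_standard(np.zeros((2, 2)), obs, tau=1.0, seed=5)
        np.testing.assert_array_equal(gs.training_data.values,
                                      gs2.training_data.values)


class TestLabelSampling:
    def test_random_counts_at_reference_scale(self):
        adj = np.zeros((50, 50), dtype=int)
        labels = sample_labels_random(adj, rho=0.2, seed=0,
                                      include_diagonal=True)
        assert labels.pair_index.m == 2500
        assert labels.m_labelled == 500
        assert labels.m_unlabelled == 2000

    def test_rho_one_leaves_nothing_unlabelled(self):
        adj = np.eye(4, dtype=int)[::-1]
        labels = sample_labels_random(adj, rho=1.0, seed=0)
        assert labels.m_unlabelled == 0

    def test_two_seeds_differ_same_size(self):
        adj = np.zeros((10, 10), dtype=int)
        l1 = sample_labels_random(adj, 0.3, seed=1)
        l2 = sample_labels_random(adj, 0.3, seed=2)
        assert l1.m_labelled == l2.m_labelled
        assert set(l1.labelled_idx) != set(l2.labelled_idx)

    def test_zero_labels_error(self):
        with pytest.raises(ValueError):
            sample_labels_random(np.zeros((2, 2)), rho=0.01, seed=0)

    def test_rowwise_row_count(self):
        adj = np.zeros((50, 50), dtype=int)
        labels = sample_labels_rowwise(adj, rho=0.5, seed=0)
        sources = {labels.pair_index.pair_of(k)[0] for k in labels.labelled_idx}
        assert len(sources) == 25

    def test_rowwise_test_sources_fully_unseen(self):
        adj = np.zeros((8, 8), dtype=int)
        labels = sample_labels_rowwise(adj, rho=0.5, seed=3)
        train_src = {labels.pair_index.pair_of(k)[0]
                     for k in labels.labelled_idx}
        test_src = {labels.pair_index.pair_of(k)[0]
                    for k in labels.unlabelled_idx}
        assert not train_src & test_src

    def test_rowwise_rho_one(self):
        labels = sample_labels_rowwise(np.zeros((5, 5), dtype=int), 1.0, seed=0)
        assert labels.m_unlabelled == 0

    def test_train_test_disjoint_and_exhaustive(self):
        adj = np.zeros((6, 6), dtype=int)
        labels = sample_labels_random(adj, 0.4, seed=0)
        L, U = set(labels.labelled_idx), set(labels.unlabelled_idx)
        assert not L & U
        assert L | U == set(range(labels.pair_index.m))

    def test_labels_match_adjacency(self):
        rng = np.random.default_rng(0)
        adj = (rng.random((6, 6)) < 0.5).astype(int)
        labels = sample_labels_random(adj, 0.5, seed=1)
        for k, y in zip(labels.labelled_idx, labels.y):
            i, j = labels.pair_index.pair_of(k)
            assert y == (1 if adj[i, j] else -1)


class TestROC:
    def test_perfect_separation(self):
        res = roc_auc(np.array([0.9, 0.8, 0.1, 0.2]), np.array([1, 1, 0, 0]))
        assert res.auc == 1.0
        np.testing.assert_array_equal(res.roc[0], [0, 0])
        np.testing.assert_array_equal(res.roc[-1], [1, 1])

    def test_reversed_ranking(self):
        res = roc_auc(np.array([0.1, 0.2, 0.9]), np.array([1, 1, 0]))
        assert res.auc == 0.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            roc_auc(np.array([0.5, 0.2]), np.array([1, 1]))

    def test_auc_equals_mannwhitney_midrank(self, rng):
        for _ in range(10):
            scores = rng.normal(size=200)
            mask = rng.random(200) < 0.3
            scores[mask] = rng.choice(scores, mask.sum())  # introduce ties
            truth = rng.random(200) < 0.4
            if truth.all() or not truth.any():
                continue
            u = mannwhitneyu(scores[truth], scores[~truth]).statistic
            expected = u / (truth.sum() * (~truth).sum())
            assert roc_auc(scores, truth).auc == pytest.approx(expected,
                                                               abs=1e-12)

    def test_absolute_mode_ranks_by_magnitude(self):
        scores = np.array([-5.0, 0.1, 4.0, -0.2])
        truth = np.array([1, 0, 1, 0])
        assert roc_auc(scores, truth, absolute=True).auc == 1.0


class TestBaselines:
    def test_identical_variables_correlate_perfectly(self, rng):
        x = rng.normal(size=50)
        data = DataMatrix(np.column_stack([x, x]), ["a", "b"])
        assert baseline_correlation(data)[0, 1] == pytest.approx(1.0)

    def test_kendall_invariant_to_monotone_transform(self, rng):
        x = rng.normal(size=50)
        data = DataMatrix(np.column_stack([x, np.exp(3 * x)]), ["a", "b"])
        assert baseline_correlation(data, "kendall")[0, 1] == pytest.approx(1.0)

    def test_independent_variables_mostly_uncorrelated(self, rng):
        data = make_obs(rng, n=1000, p=20)
        pairs = build_pair_index(20)
        r = np.abs(baseline_correlation(data, pairs=pairs))
        assert (r < 0.1).mean() >= 0.95

    def test_zero_variance_rejected(self):
        data = DataMatrix(np.column_stack([np.ones(10), np.arange(10.0)]),
                          ["flat", "x"])
        with pytest.raises(ValueError, match="flat"):
            baseline_correlation(data)

    def test_knn_identical_pair_inherits_label(self):
        pairs = build_pair_index(2, include_diagonal=True)  # m = 4
        X = np.array([[0.0, 0.0], [5.0, 5.0], [0.0, 0.0], [9.0, 9.0]])
        feats = PairFeatureMatrix(X, pairs, stage="pca")
        labels = PartialLabels(pairs, np.array([0, 1]), np.array([1, -1]))
        scores = baseline_knn(feats, labels, k=1)
        # unlabelled pair 2 coincides with labelled +1 pair 0
        assert scores[0] == 1.0

    def test_knn_with_all_neighbours_gives_mean_label(self, rng):
        pairs = build_pair_index(3)  # m = 6
        feats = PairFeatureMatrix(rng.normal(size=(6, 4)), pairs, stage="pca")
        labels = PartialLabels(pairs, np.array([0, 1, 2]),
                               np.array([1, 1, -1]))
        scores = baseline_knn(feats, labels, k=3)
        np.testing.assert_allclose(scores, 1 / 3)

    def test_knn_matches_brute_force(self, rng):
        pairs = build_pair_index(4)  # m = 12
        X = rng.normal(size=(12, 3))
        feats = PairFeatureMatrix(X, pairs, stage="pca")
        L = np.array([0, 2, 5, 7, 9])
        y = np.array([1, -1, 1, 1, -1])
        labels = PartialLabels(pairs, L, y)
        scores = baseline_knn(feats, labels, k=2)
        for a, u in enumerate(labels.unlabelled_idx):
            d = np.linalg.norm(X[L] - X[u], axis=1)
            nearest = np.argsort(d, kind="stable")[:2]
            assert scores[a] == pytest.approx(y[nearest].mean())

    def test_knn_k_exceeding_labels_rejected(self, rng):
        pairs = build_pair_index(3)
        feats = PairFeatureMatrix(rng.normal(size=(6, 2)), pairs, stage="pca")
        labels = PartialLabels(pairs, np.array([0]), np.array([1]))
        with pytest.raises(ValueError, match="exceeds"):
            baseline_knn(feats, labels, k=2)


class TestScreens:
    def test_sparsity_screen_thresholds(self):
        adj = np.zeros((10, 10), dtype=int)
        assert not passes_sparsity_screen(adj)
        adj[0, 1] = adj[0, 2] = adj[1, 2] = 1  # 3/90 > 2.5%
        assert passes_sparsity_screen(adj)

    def test_rowwise_screen(self):
        adj = np.zeros((4, 4), dtype=int)
        adj[0, 1] = 1
        assert not passes_rowwise_screen(adj)
        adj[1, 2] = 1
        assert passes_rowwise_screen(adj)
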