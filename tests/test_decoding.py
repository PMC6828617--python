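import numpy as np
import pytest
from scipy import stats

import fcmvpa as f
from fcmvpa.decoding import SelectionConfig

from conftest import separable_features


class TestOneSampleT:
    def test_hand_computed_example(self):
        t, p = f.one_sample_t(np.array([1.0, 1.0, 2.0, 2.0]))
        # mean 1.5, sd 0.5774, n 4 -> t = 1.5 / (0.5774/2) = 5.196
        assert t == pytest.approx(5.196152, abs=1e-5)
        assert p == pytest.approx(2 * stats.t.sf(5.196152, df=3), rel=1e-6)

    def test_symmetric_values_give_zero_t(self):
        t, p = f.one_sample_t(np.array([-1.0, 1.0, -2.0, 2.0]))
        assert t == 0.0 and p == 1.0

    def test_constant_nonzero_flagged_infinite(self):
        t, p = f.one_sample_t(np.array([3.0, 3.0, 3.0]))
        assert np.isinf(t) and t > 0 and p == 0.0
        t, _ = f.one_sample_t(np.array([-3.0, -3.0]))
        assert np.isinf(t) and t < 0

    def test_constant_zero_gives_p_one(self):
        t, p = f.one_sample_t(np.zeros(5))
        assert t == 0.0 and p == 1.0

    def test_matches_scipy_vectorized(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((15, 40))
        t, p = f.one_sample_t(X)
        ref = stats.ttest_1samp(X, 0.0, axis=0)
        assert np.abs(t - ref.statistic).max() < 1e-10
        assert np.abs(p - ref.pvalue).max() < 1e-10


def brute_force_bh(p, q):
    """Independent step-up oracle: largest k with p_(k) <= k q / m."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k_star = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


class TestBhFdr:
    def test_worked_example(self):
        mask = f.bh_fdr(np.array([0.001, 0.02, 0.5]), q=0.05)
        assert mask.tolist() == [True, True, False]

    def test_degenerate_inputs(self):
        assert not f.bh_fdr(np.ones(4), q=0.05).any()
        assert f.bh_fdr(np.array([0.0]), q=0.01).all()
        assert f.bh_fdr(np.array([]), q=0.05).size == 0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 60))
            p[rng.uniform(size=len(p)) < 0.3] /= 100
            q = rng.choice([0.01, 0.05, 0.1])
            assert np.array_equal(f.bh_fdr(p, q), brute_force_bh(p, q))


class TestPositiveUnion:
    def test_union_semantics(self):
        rng = np.random.default_rng(2)
        n_sub, n_edge = 16, 30
        a = rng.normal(0, 0.1, (n_sub, n_edge))
        b = rng.normal(0, 0.1, (n_sub, n_edge))
        a[:, 3] += 2.0   # condition A significant on edge 3
        b[:, 7] += 2.0   # condition B significant on edge 7
        mask = f.positive_union_mask({"A": a, "B": b}, q=0.01)
        assert mask[3] and mask[7]

    def test_negative_edges_excluded_despite_large_t(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 0.05, (16, 10))
        a[:, 0] -= 3.0  # hugely significant but negative
        a[:, 1] += 3.0
        mask = f.positive_union_mask({"A": a}, q=0.01)
        assert not mask[0] and mask[1]

    def test_null_selection_rate_small(self):
        """Pure-noise training data at q=0.01 selects almost nothing."""
        rng = np.random.default_rng(4)
        rates = []
        for _ in range(10):
            feats = {c: rng.standard_normal((19, 1000)) for c in "ABC"}
            try:
                mask = f.positive_union_mask(feats, q=0.01)
                rates.append(mask.mean())
            except ValueError:
                rates.append(0.0)
        assert np.mean(rates) < 0.05

    def test_single_condition_decomposes_to_gated_bh(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.1, 0.3, (12, 200))
        mask = f.positive_union_mask({"A": a}, q=0.05)
        t, p = f.one_sample_t(a)
        assert np.array_equal(mask, (t > 0) & f.bh_fdr(p, 0.05))

    def test_empty_selection_raises(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError, match="empty"):
            f.positive_union_mask({"A": rng.normal(-1, 0.1, (10, 20))}, q=0.01)


class TestFScore:
    def test_constant_feature_scores_zero(self):
        X = np.ones((8, 1))
        y = np.array(["a"] * 4 + ["b"] * 4)
        assert f.f_scores(X, y)[0] == 0.0

    def test_two_class_formula(self):
        # class means 0 and 2, both within-variances 1, overall mean 1:
        # score = ((0-1)^2 + (2-1)^2) / (1 + 1) = 1.0
        a = 1 / np.sqrt(2)
        X = np.array([[-a], [a], [2 - a], [2 + a]])
        y = np.array(["u", "u", "v", "v"])
        assert f.f_scores(X, y)[0] == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((20, 5))
        y = np.array(["a"] * 10 + ["b"] * 10)
        s1 = f.f_scores(X, y)
        s2 = f.f_scores(X * -3.7 + 11.0, y)
        assert np.allclose(s1, s2, atol=1e-10)

    def test_three_class_matches_anova_f(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((30, 6))
        y = np.repeat(["a", "b", "c"], 10)
        s = f.f_scores(X, y)
        ref = stats.f_oneway(X[:10], X[10:20], X[20:])
        assert np.abs(s - ref.statistic).max() < 1e-10

    def test_zero_within_variance_distinct_means_ranked_first(self):
        X = np.column_stack([
            np.array([0.0, 0.0, 1.0, 1.0]),      # infinite score
            np.array([0.1, -0.2, 0.5, 0.4]),
        ])
        y = np.array(["a", "a", "b", "b"])
        order = f.f_score_rank(X, y)
        assert order[0] == 0
        assert np.isinf(f.f_scores(X, y)[0])

    def test_ties_broken_by_index(self):
        X = np.zeros((6, 3))
        y = np.array(["a"] * 3 + ["b"] * 3)
        assert f.f_score_rank(X, y).tolist() == [0, 1, 2]


class TestLinearSVM:
    def test_separable_points_classified(self):
        svm = f.train_linear_classifier(np.array([[-1.0], [1.0]]), np.array([0, 1]))
        assert (svm.decision(np.array([[-1.0], [1.0]])) > 0).tolist() == [False, True]

    def test_duplicating_samples_keeps_decision(self):
        # holds in the separable regime, where no slack is active and the
        # margin support vectors fully determine the solution
        rng = np.random.default_rng(9)
        X = rng.standard_normal((10, 3))
        X[5:] += 6.0
        y = np.array(["a"] * 5 + ["b"] * 5)
        s1 = f.train_linear_classifier(X, y)
        s2 = f.train_linear_classifier(np.vstack([X, X]), np.concatenate([y, y]))
        grid = rng.standard_normal((20, 3))
        assert np.abs(s1.decision(grid) - s2.decision(grid)).max() < 1e-6

    def test_margin_midpoint_inside_gap(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        y = np.array(["neg", "neg", "pos", "pos"])
        svm = f.train_linear_classifier(X, y)
        boundary = -svm.bias / svm.weights[0]
        assert -1.0 < boundary < 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            f.train_linear_classifier(np.zeros((4, 2)), np.array(["a"] * 4))


class TestLoocv:
    def test_fold_count_and_held_out_once(self):
        X, classes = separable_features(n_subj=8)
        res = f.loocv_decode(X, classes, classes)
        assert len(res.fold_results) == 8
        held = [fr.held_out_subject for fr in res.fold_results]
        assert len(set(held)) == 8
        for fr in res.fold_results:
            assert fr.held_out_subject not in fr.training_subjects
            assert len(fr.training_subjects) == 7

    def test_separable_cohort_decodes_perfectly(self):
        X, classes = separable_features(n_subj=10, delta=2.0)
        res = f.loocv_decode(X, classes, classes)
        assert res.accuracy == 1.0
        assert res.mode == "multi_category"
        assert res.chance_level == pytest.approx(1 / 3)

    def test_pairwise_mode(self):
        X, classes = separable_features(n_subj=8, delta=2.0)
        res = f.loocv_decode(X, classes, ("a", "b"))
        assert res.mode == "pairwise"
        assert res.accuracy == 1.0
        # only pair-class maps are scored
        assert all(len(fr.true_labels) == 2 for fr in res.fold_results)

    def test_pairwise_invariant_to_third_class_relabeling(self):
        X, classes = separable_features(n_subj=8, delta=1.0, seed=3)
        res1 = f.loocv_decode(X, classes, ("a", "b"))
        # scramble class c's data entirely
        X2 = X.copy()
        X2[:, 2, :] = np.random.default_rng(99).standard_normal(X[:, 2, :].shape)
        res2 = f.loocv_decode(X2, classes, ("a", "b"))
        assert res1.accuracy == res2.accuracy
        for f1, f2 in zip(res1.fold_results, res2.fold_results):
            assert f1.predicted_labels == f2.predicted_labels

    def test_selection_fitted_on_training_subjects_only(self):
        X, classes = separable_features(n_subj=6)
        res = f.loocv_decode(X, classes, classes)
        for fr in res.fold_results:
            assert fr.held_out_subject not in fr.training_subjects
            for pair, svm in fr.pair_weights.items():
                assert len(svm.weights) == len(fr.selected_edges)

    def test_f_score_selection_defaults_k_to_union_size(self):
        X, classes = separable_features(n_subj=8)
        r1 = f.loocv_decode(X, classes, classes,
                            SelectionConfig(method="f_score_topk"))
        r2 = f.loocv_decode(X, classes, classes)
        for a, b in zip(r1.fold_results, r2.fold_results):
            assert len(a.selected_edges) == len(b.selected_edges)

    def test_too_few_subjects_rejected(self):
        X, classes = separable_features(n_subj=2)
        with pytest.raises(ValueError):
            f.loocv_decode(X[:1], classes, classes)


class TestAccuracyCurve:
    def test_curve_length_matches_grid(self):
        X, classes = separable_features(n_subj=6)
        curve = f.accuracy_curve(X, classes, classes, k_grid=[5, 20, 50])
        assert [k for k, _ in curve] == [5, 20, 50]

    def test_full_k_equals_select_all_loocv(self):
        X, classes = separable_features(n_subj=6)
        n_edges = X.shape[2]
        curve = f.accuracy_curve(X, classes, classes, k_grid=[n_edges])
        ref = f.loocv_decode(
            X, classes, classes, SelectionConfig(method="f_score_topk", k=n_edges)
        )
        assert curve[0][1] == ref.accuracy

    def test_oversized_k_clamped_with_warning(self):
        X, classes = separable_features(n_subj=6)
        with pytest.warns(UserWarning, match="clamped"):
            curve = f.accuracy_curve(X, classes, classes, k_grid=[10**6])
        assert curve[0][0] == X.shape[2]

    def test_peak_accuracy_well_above_chance_on_separable_data(self):
        X, classes = separable_features(n_subj=10, delta=2.0)
        curve = f.accuracy_curve(X, classes, classes, k_grid=[4, 16, 64])
        assert max(acc for _, acc in curve) >= 1 / 3 + 0.3
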