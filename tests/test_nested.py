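"""SMOTE, ROC/CI oracles, SVM grid search and the nested-CV driver."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from exoscreen.nested import (ClassifierSpec, CVScheme, MetricSet,
                              comprehensive_score, evaluate_roc, fit_rbf_svm,
                              fold_auc_ci, run_nested, smote_oversample,
                              sweep_panel_size)
from exoscreen.simulate import permute_labels


def _auc_concordance(scores, y):
    """Pairwise-concordance AUC with ties counted 1/2 (O(n^2) oracle)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestSmote:
    def test_balanced_input_unchanged(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.array([0, 1] * 5)
        X2, y2 = smote_oversample(X, y, 3, 0)
        np.testing.assert_array_equal(X2, X)
        np.testing.assert_array_equal(y2, y)

    def test_output_balanced_and_originals_verbatim(self, rng):
        X = rng.normal(size=(60, 4))
        y = np.array([1] * 12 + [0] * 48)
        X2, y2 = smote_oversample(X, y, 5, 3)
        assert (y2 == 0).sum() == (y2 == 1).sum() == 48
        np.testing.assert_array_equal(X2[:60], X)

    def test_two_minority_points_interpolate_on_segment(self, rng):
        a, b = np.array([0.0, 0.0]), np.array([2.0, 4.0])
        X = np.vstack([a, b, rng.normal(10, 1, size=(20, 2))])
        y = np.array([1, 1] + [0] * 20)
        X2, y2 = smote_oversample(X, y, 1, 7)
        synth = X2[22:]
        # every synthetic point is a + t (b - a) for t in [0, 1]
        t = synth[:, 0] / 2.0
        np.testing.assert_allclose(synth[:, 1], 4.0 * t, atol=1e-12)
        assert np.all((t >= 0) & (t <= 1))

    def test_minority_of_one_raises(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(ValueError):
            smote_oversample(X, np.array([1, 0, 0, 0, 0]), 5, 0)


class TestEvaluateRoc:
    def test_perfect_ranking(self):
        m = evaluate_roc(np.array([0.1, 0.2, 0.8, 0.9]),
                         np.array([0, 0, 1, 1]))
        assert m.auc == 1.0
        assert m.sensitivity == 1.0 and m.specificity == 1.0

    def test_worked_example_three_quarters(self):
        m = evaluate_roc(np.array([0.1, 0.4, 0.35, 0.8]),
                         np.array([0, 0, 1, 1]))
        assert m.auc == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        m = evaluate_roc(np.full(10, 0.5), np.array([0, 1] * 5))
        assert m.auc == pytest.approx(0.5)

    def test_roc_points_monotone_and_bounded(self, rng):
        s = rng.normal(size=50)
        y = (rng.random(50) < 0.4).astype(int)
        m = evaluate_roc(s, y)
        pts = m.roc_points
        assert np.all(np.diff(pts[:, 0]) >= 0)
        assert np.all(np.diff(pts[:, 1]) >= 0)
        np.testing.assert_allclose(pts[0], [0, 0])
        np.testing.assert_allclose(pts[-1], [1, 1])

    def test_trapezoid_equals_concordance_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 200))
            y = np.zeros(n, dtype=int)
            y[: max(1, int(rng.integers(1, n)))] = 1
            rng.shuffle(y)
            if len(np.unique(y)) < 2:
                continue
            scores = np.round(rng.normal(size=n), int(rng.integers(0, 3)))
            m = evaluate_roc(scores, y)
            assert m.auc == pytest.approx(_auc_concordance(scores, y),
                                          abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            evaluate_roc(np.array([0.1, 0.2]), np.array([1, 1]))


class TestFoldCI:
    def test_hand_computed_t_interval(self):
        lo, hi = fold_auc_ci([0.90, 0.92, 0.94, 0.96, 0.98])
        assert lo == pytest.approx(0.9007, abs=1e-3)
        assert hi == pytest.approx(0.9793, abs=1e-3)

    def test_zero_width_for_equal_folds(self):
        lo, hi = fold_auc_ci([0.8, 0.8, 0.8])
        assert lo == pytest.approx(0.8, abs=1e-12)
        assert hi == pytest.approx(0.8, abs=1e-12)

    def test_contains_mean_and_clips(self):
        lo, hi = fold_auc_ci([0.95, 0.99, 1.0, 0.97])
        assert lo <= np.mean([0.95, 0.99, 1.0, 0.97]) <= hi
        assert hi <= 1.0

    def test_requires_two_folds(self):
        with pytest.raises(ValueError):
            fold_auc_ci([0.9])


class TestFitRbfSvm:
    def _toy(self, rng, n=60, gap=6.0):
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 2))
        X[y == 1] += gap
        return X, y

    def test_separable_data_fits_perfectly(self, rng):
        X, y = self._toy(rng)
        model = fit_rbf_svm(X, y, ClassifierSpec(rebalance="none"),
                            CVScheme(seed=0), seed=0)
        assert ((model.predict_proba(X) > 0.5) == y).mean() == 1.0

    def test_grid_choice_matches_bruteforce(self, rng):
        X, y = self._toy(rng, n=40)
        spec = ClassifierSpec(c_grid=(0.5, 5.0), gamma_grid=(0.01, 1.0),
                              rebalance="none")
        scheme = CVScheme(inner_folds=3, seed=2)
        model = fit_rbf_svm(X, y, spec, scheme, seed=2)

        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=2)
        Xs = model.scaler.transform(X)
        best, best_pair = -np.inf, None
        for c in spec.c_grid:
            for g in spec.gamma_grid:
                aucs = []
                for tr, te in skf.split(Xs, y):
                    m = SVC(kernel="rbf", C=c, gamma=g).fit(Xs[tr], y[tr])
                    fpr, tpr, _ = roc_curve(y[te], m.decision_function(Xs[te]),
                                            drop_intermediate=False)
                    aucs.append(np.trapezoid(tpr, fpr))
                if np.mean(aucs) > best:
                    best, best_pair = np.mean(aucs), (c, g)
        assert (model.c, model.gamma) == best_pair

    def test_deterministic_given_seed(self, rng):
        X, y = self._toy(rng)
        m1 = fit_rbf_svm(X, y, seed=5)
        m2 = fit_rbf_svm(X, y, seed=5)
        assert (m1.c, m1.gamma) == (m2.c, m2.gamma)
        np.testing.assert_array_equal(m1.predict_proba(X), m2.predict_proba(X))

    def test_constant_features_raise(self):
        X = np.ones((20, 2))
        y = np.array([0, 1] * 10)
        with pytest.raises(ValueError):
            fit_rbf_svm(X, y)


class TestRunNested:
    def test_fixed_panel_accounting(self, small_processed):
        filt, norm, meta, _, truth = small_processed
        scheme = CVScheme(outer_folds=10, seed=3)
        res = run_nested(norm, meta, panel=truth.planted_features, scheme=scheme)
        assert len(res.fold_metrics) == 10
        assert len(res.fold_params) == 10
        assert all(f == truth.planted_features for f in res.fold_features)
        lo, hi = res.auc_ci
        assert lo <= res.mean_auc <= hi
        # folds partition the cohort; test partitions contain only originals
        assert sorted(res.pooled_sample_ids) == sorted(norm.sample_ids)

    def test_planted_panel_reaches_high_auc(self, small_processed):
        filt, norm, meta, _, truth = small_processed
        res = run_nested(norm, meta, panel=truth.planted_features,
                         scheme=CVScheme(seed=1))
        assert res.mean_auc >= 0.9

    def test_stratification_preserves_class_ratio(self, small_processed):
        filt, norm, meta, _, truth = small_processed
        res = run_nested(norm, meta, panel=truth.planted_features,
                         scheme=CVScheme(seed=2))
        y = meta.y
        lookup = dict(zip(meta.sample_id, y))
        # every sample held out exactly once, so pooled cases match the cohort
        assert sum(lookup[s] for s in res.pooled_sample_ids) == y.sum()
        assert len(res.pooled_sample_ids) == len(norm.sample_ids)

    def test_auto_select_on_permuted_labels_is_null(self, small_processed):
        """Selection inside folds keeps permuted-label AUC near chance."""
        filt, norm, meta, _, _ = small_processed
        aucs = []
        for seed in range(3):
            pmeta = permute_labels(meta, seed=seed)
            res = run_nested(norm, pmeta, counts=filt, panel_size=3,
                             scheme=CVScheme(outer_folds=5, seed=seed))
            aucs.append(res.mean_auc)
        assert 0.35 <= np.mean(aucs) <= 0.65

    def test_auto_select_requires_counts(self, small_processed):
        _, norm, meta, _, _ = small_processed
        with pytest.raises(ValueError):
            run_nested(norm, meta)

    def test_unknown_panel_feature_raises(self, small_processed):
        _, norm, meta, _, _ = small_processed
        with pytest.raises(KeyError):
            run_nested(norm, meta, panel=["nope"])


class TestSweep:
    def test_nine_rows_and_bruteforce_argmax(self, small_processed):
        filt, norm, meta, _, truth = small_processed
        ranked = list(truth.planted_features) + [
            f for f in norm.feature_ids if f not in truth.planted_features][:7]
        sweep = sweep_panel_size(norm, meta, ranked,
                                 scheme=CVScheme(outer_folds=3, seed=4))
        assert len(sweep.table) == 9
        assert list(sweep.table["k"]) == list(range(2, 11))
        brute = sweep.table.loc[sweep.table["comprehensive_score"].idxmax(), "k"]
        assert sweep.best_k == brute

    def test_comprehensive_score_definition(self):
        m = MetricSet(0.9, 0.8, 0.7, 0.75, np.zeros((2, 2)), 0.5)
        assert comprehensive_score(m) == pytest.approx((0.9 + 0.8 + 0.7) / 3)

    def test_k_range_validation(self, small_processed):
        _, norm, meta, _, truth = small_processed
        with pytest.raises(ValueError):
            sweep_panel_size(norm, meta, truth.planted_features,
                             k_range=range(2, 11))
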