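import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

import leukopred as lp
from conftest import prepare
from leukopred.classify import (SVMGrid, TrainedModel, _as_sample_matrix,
                                default_grid, encode_labels)


def pair_count_auc(scores, labels):
    """Exhaustive pair-counting oracle for AUC."""
    scores, y = np.asarray(scores, float), np.asarray(labels, int)
    pos, neg = scores[y == 1], scores[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += (a > b) + 0.5 * (a == b)
    return total / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_ranking(self):
        assert lp.compute_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert lp.compute_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_hand_worked_example(self):
        assert lp.compute_auc([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0]) == 0.75

    def test_matches_pair_counting_on_random_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(4, 30)
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            assert lp.compute_auc(scores, y) == pytest.approx(
                pair_count_auc(scores, y), abs=1e-12
            )

    def test_complement_and_monotone_invariance(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 20)
        y[:2] = [0, 1]
        scores = rng.normal(size=20)
        auc = lp.compute_auc(scores, y)
        assert auc + lp.compute_auc(-scores, y) == pytest.approx(1.0)
        assert lp.compute_auc(np.exp(3 * scores), y) == pytest.approx(auc)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            lp.compute_auc([0.1, 0.2], [1, 1])


class TestReport:
    def test_perfect_validation_shaped_case(self):
        scores = [0.9] * 7 + [0.1] * 6
        labels = [1] * 7 + [0] * 6
        rep = lp.compute_report(scores, labels)
        assert (rep.tp, rep.fn, rep.tn, rep.fp) == (7, 0, 6, 0)
        assert rep.sensitivity == rep.f1 == rep.kappa == 1.0

    def test_chance_agreement_gives_zero_kappa(self):
        scores = [0.9] * 5 + [0.1] * 5 + [0.9] * 5 + [0.1] * 5
        labels = [1] * 10 + [0] * 10
        rep = lp.compute_report(scores, labels)
        assert (rep.tp, rep.fn, rep.fp, rep.tn) == (5, 5, 5, 5)
        assert rep.kappa == pytest.approx(0.0)

    def test_hand_computed_kappa_and_f1(self):
        # TP=6, FN=1, TN=5, FP=1
        scores = [0.9] * 6 + [0.1] + [0.9] + [0.1] * 5
        labels = [1] * 7 + [0] * 6
        rep = lp.compute_report(scores, labels)
        assert (rep.tp, rep.fn, rep.fp, rep.tn) == (6, 1, 1, 5)
        n, p_o = 13, 11 / 13
        p_e = (7 * 7 + 6 * 6) / 13**2
        assert rep.kappa == pytest.approx((p_o - p_e) / (1 - p_e))
        assert rep.f1 == pytest.approx(12 / 14)
        assert rep.sensitivity == pytest.approx(6 / 7)

    def test_roc_monotone_from_origin_to_one(self):
        rng = np.random.default_rng(2)
        y = np.array([1] * 8 + [0] * 12)
        scores = rng.random(20)
        rep = lp.compute_report(scores, y)
        assert rep.roc_fpr[0] == 0.0 and rep.roc_tpr[0] == 0.0
        assert rep.roc_fpr[-1] == 1.0 and rep.roc_tpr[-1] == 1.0
        assert (np.diff(rep.roc_fpr) >= 0).all() and (np.diff(rep.roc_tpr) >= 0).all()

    def test_metrics_match_sklearn_on_random_sets(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(6, 40))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            scores = rng.random(n)
            rep = lp.compute_report(scores, y)
            pred = (scores > 0.5).astype(int)
            assert rep.kappa == pytest.approx(sk.cohen_kappa_score(y, pred), abs=1e-12)
            assert rep.f1 == pytest.approx(
                sk.f1_score(y, pred, zero_division=0), abs=1e-12
            )
            assert rep.auc == pytest.approx(sk.roc_auc_score(y, scores), abs=1e-12)


class TestTrainModel:
    def separable_data(self, seed=0, n=28):
        rng = np.random.default_rng(seed)
        y = np.array([1] * (n // 2) + [0] * (n - n // 2))
        X = pd.DataFrame(
            {
                "M1": np.where(y == 1, 1.0, -1.0) + rng.normal(0, 0.05, n),
                "M2": rng.normal(0, 1, n),
            }
        )
        return (X - X.mean()) / X.std(ddof=1), y

    @pytest.mark.parametrize("algorithm", lp.ALGORITHMS)
    def test_separable_feature_gives_training_auc_one(self, algorithm):
        X, y = self.separable_data()
        model = lp.train_model(X, y, ["M1"], algorithm, folds=7, seed=0)
        assert lp.compute_auc(model.predict_scores(X), y) == 1.0

    def test_empty_feature_list_rejected(self):
        X, y = self.separable_data()
        with pytest.raises(ValueError, match="non-empty"):
            lp.train_model(X, y, [], "random_forest")

    def test_missing_feature_rejected(self):
        X, y = self.separable_data()
        with pytest.raises(KeyError, match="M9"):
            lp.train_model(X, y, ["M9"], "random_forest", folds=7)

    def test_single_class_rejected(self):
        X, _ = self.separable_data()
        with pytest.raises(ValueError, match="classes"):
            lp.train_model(X, np.ones(len(X), int), ["M1"], "svm_linear", folds=7)

    def test_selected_hyperparameters_come_from_grid(self):
        X, y = self.separable_data(seed=1)
        grid = SVMGrid(C=(0.001, 0.1))
        model = lp.train_model(X, y, ["M1", "M2"], "svm_linear", grid, folds=7, seed=1)
        assert model.params["C"] in grid.C
        assert len(model.cv_table) == 2

    def test_scores_invariant_to_sample_order(self):
        X, y = self.separable_data(seed=2)
        model = lp.train_model(X, y, ["M1", "M2"], "random_forest", folds=7, seed=2)
        scores = model.predict_scores(X)
        perm = np.random.default_rng(0).permutation(len(X))
        np.testing.assert_allclose(model.predict_scores(X.iloc[perm]), scores[perm])

    def test_null_glm_scores_are_half(self):
        est = LogisticRegression()
        est.classes_ = np.array([0, 1])
        est.coef_ = np.zeros((1, 2))
        est.intercept_ = np.zeros(1)
        est.n_features_in_ = 2
        model = TrainedModel("glm_elastic_net", ["a", "b"], {}, est, pd.DataFrame())
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 2)), columns=["a", "b"])
        np.testing.assert_allclose(model.predict_scores(X), 0.5)

    def test_deterministic_given_seed(self):
        X, y = self.separable_data(seed=3)
        a = lp.train_model(X, y, ["M1", "M2"], "random_forest", folds=7, seed=4)
        b = lp.train_model(X, y, ["M1", "M2"], "random_forest", folds=7, seed=4)
        pd.testing.assert_frame_equal(a.cv_table, b.cv_table)
        np.testing.assert_array_equal(a.predict_scores(X), b.predict_scores(X))


class TestTranscriptClassifier:
    def test_combined_markers_at_least_match_single_markers(self, planted_cohort):
        parts = prepare(planted_cohort)
        up, down = list(planted_cohort.truth["gene_id"])
        aucs = {}
        for feats in ([up], [down], [up, down]):
            res = lp.TranscriptClassifier(parts["z_train"], parts["y_train"], feats,
                                          "random_forest", seed=0).fit()
            aucs[tuple(feats)] = res.evaluate(parts["z_valid"], parts["y_valid"]).auc
        assert aucs[(up, down)] >= max(aucs[(up,)], aucs[(down,)]) - 0.1

    def test_results_summary_mentions_selected_params(self, planted_cohort):
        parts = prepare(planted_cohort)
        feats = list(planted_cohort.truth["gene_id"])
        res = lp.TranscriptClassifier(parts["z_train"], parts["y_train"], feats,
                                      "svm_linear", seed=0).fit()
        text = res.summary()
        assert "svm_linear" in text and "C=" in text
        assert 0.0 <= res.auc_cv <= 1.0 and 0.0 <= res.auc_resub <= 1.0
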