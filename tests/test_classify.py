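"""Classification harness components: elimination trace arithmetic,
randomized tuning, soft voting, evaluation metrics against brute-force
oracles, feature ranking, and classifier comparison."""

import numpy as np
import pandas as pd
import pytest

from voicescreen.classify import (EnsembleModel, FoldMember, ModelSpec,
                                  compare_classifiers, evaluate,
                                  make_estimator, nested_cv, rank_features,
                                  rfe, soft_vote, tune)


def _toy(n=60, p=20, informative=(0, 1), seed=0, sep=3.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = np.repeat([0, 1], n // 2)
    for j in informative:
        X[:, j] += sep * y
    cols = [f"f{i:03d}" for i in range(p)]
    return pd.DataFrame(X, columns=cols), y, [cols[j] for j in informative]


class TestRFE:
    def test_evaluated_sizes_count_for_20_features(self):
        X, y, _ = _toy(p=20)
        tr = (X.iloc[:40], y[:40])
        va = (X.iloc[40:], y[40:])
        trace = rfe(tr, va, ModelSpec("logreg"))
        # arithmetic progression 20, 18, ..., 6 -> 8 evaluated sizes
        assert trace.sizes == list(range(20, 5, -2))
        assert len(trace.sizes) == 8
        assert trace.sizes[-1] == 6

    def test_sizes_decrease_by_two(self):
        X, y, _ = _toy(p=14)
        trace = rfe((X.iloc[:40], y[:40]), (X.iloc[40:], y[40:]),
                    ModelSpec("logreg"))
        assert all(a - b == 2 for a, b in zip(trace.sizes, trace.sizes[1:]))

    def test_fewer_than_eight_features_single_iteration(self):
        X, y, _ = _toy(p=7)
        trace = rfe((X.iloc[:40], y[:40]), (X.iloc[40:], y[40:]),
                    ModelSpec("logreg"))
        assert trace.sizes == [7]
        assert trace.selected_set == list(X.columns)

    def test_informative_features_survive_elimination(self):
        X, y, informative = _toy(n=80, p=20, sep=4.0, seed=3)
        trace = rfe((X.iloc[:60], y[:60]), (X.iloc[60:], y[60:]),
                    ModelSpec("logreg"))
        assert set(informative) <= set(trace.selected_set)

    def test_selection_is_argmax_accuracy_earliest_on_ties(self):
        X, y, _ = _toy(p=12, sep=5.0)
        trace = rfe((X.iloc[:40], y[:40]), (X.iloc[40:], y[40:]),
                    ModelSpec("logreg"))
        best = int(np.argmax(trace.accuracies))
        assert trace.selected_set == trace.feature_sets[best]


class TestTune:
    def test_linear_families_return_defaults(self):
        X, y, _ = _toy()
        assert tune((X, y), ModelSpec("svm_linear")) == {}
        assert tune((X, y), ModelSpec("logreg")) == {}

    def test_same_seed_same_choice(self):
        X, y, _ = _toy(n=40, p=6)
        spec = ModelSpec("gradient_boosted_trees", seed=5)
        a = tune((X, y), spec, n_draws=3, n_inner=3)
        b = tune((X, y), spec, n_draws=3, n_inner=3)
        assert a == b
        assert set(a) == {"tree_depth", "l2_leaf_regularization",
                          "bagging_temperature", "random_strength"}

    def test_single_draw_returned(self):
        X, y, _ = _toy(n=40, p=6)
        spec = ModelSpec("gradient_boosted_trees", seed=2)
        params = tune((X, y), spec, n_draws=1, n_inner=3)
        expected = __import__("voicescreen.classify", fromlist=["draw_tree_params"]
                              ).draw_tree_params(np.random.default_rng(2))
        assert params == expected

    def test_non_tree_tunables_rejected(self):
        with pytest.raises(ValueError, match="no tuned parameters"):
            ModelSpec("svm_linear", tunable={"C": 2.0})


class TestSoftVote:
    def _ensemble(self, probas, classes=(0, 1)):
        class Fixed:
            def __init__(self, p, cls):
                self.p = np.asarray(p)
                self.cls = np.asarray(cls)

            def predict_proba(self, X):
                return np.tile(self.p, (len(X), 1))

        members = []
        for p in probas:
            model = Fixed(p, classes)
            pipe = type("P", (), {})()
            pipe.predict_proba = model.predict_proba
            pipe.named_steps = {"clf": type("C", (), {"classes_": np.asarray(classes)})()}
            members.append(FoldMember(features=["a"], params={}, model=pipe,
                                      decisions=None, validation_accuracy=1.0,
                                      test_accuracy=1.0,
                                      importance=pd.Series({"a": 1.0})))
        return EnsembleModel(members=members, classes=np.asarray(classes),
                             feature_names=["a"])

    def test_mean_of_member_probabilities(self):
        ens = self._ensemble([[0.2, 0.8], [0.6, 0.4]])
        out = soft_vote(ens, pd.DataFrame({"a": [0.0]}))
        assert np.allclose(out, [[0.4, 0.6]])

    def test_identical_members_identity(self):
        ens = self._ensemble([[0.3, 0.7]] * 4)
        out = soft_vote(ens, pd.DataFrame({"a": [0.0, 1.0]}))
        assert np.allclose(out, 0.5 * np.array([[0.6, 1.4], [0.6, 1.4]]))

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(0)
        raw = rng.dirichlet([1, 1, 1], size=5)
        ens = self._ensemble(list(raw), classes=(0, 1, 2))
        out = soft_vote(ens, pd.DataFrame({"a": np.zeros(3)}))
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-9)

    def test_missing_feature_rejected(self):
        ens = self._ensemble([[0.5, 0.5]])
        with pytest.raises(ValueError, match="lacks features"):
            soft_vote(ens, pd.DataFrame({"b": [0.0]}))


def _pairs_auc(y, s):
    """Brute-force AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos, neg = s[y == 1], s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        proba = np.eye(3)[y]
        out = evaluate(y, proba, np.array([0, 1, 2]))
        assert out["accuracy"] == 1.0
        assert np.trace(out["confusion"]) == 6
        assert out["roc"]["micro_auc"] == 1.0 and out["roc"]["macro_auc"] == 1.0

    def test_label_independent_probabilities_near_chance_auc(self):
        rng = np.random.default_rng(0)
        n = 2000
        y = rng.integers(0, 2, n)
        p1 = rng.random(n)
        proba = np.column_stack([1 - p1, p1])
        out = evaluate(y, proba, np.array([0, 1]))
        assert out["roc"]["micro_auc"] == pytest.approx(0.5, abs=0.05)

    def test_three_class_micro_auc_matches_pairs_oracle(self):
        rng = np.random.default_rng(4)
        y = np.array([0, 0, 1, 1, 2, 2])
        proba = rng.dirichlet([1, 1, 1], size=6)
        out = evaluate(y, proba, np.array([0, 1, 2]))
        Y = np.eye(3)[y].ravel()
        assert out["roc"]["micro_auc"] == pytest.approx(
            _pairs_auc(Y, proba.ravel()))

    def test_confusion_trace_equals_accuracy(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 3, 60)
        proba = rng.dirichlet([1, 1, 1], size=60)
        out = evaluate(y, proba, np.array([0, 1, 2]))
        cm = out["confusion"]
        assert np.trace(cm) / cm.sum() == pytest.approx(out["accuracy"])
        assert np.array_equal(cm.sum(axis=1), np.bincount(y, minlength=3))

    def test_single_class_labels_flagged(self):
        with pytest.warns(UserWarning, match="ROC undefined"):
            out = evaluate(np.zeros(5, dtype=int),
                           np.tile([0.5, 0.5], (5, 1)), np.array([0, 1]))
        assert out["roc"] is None


class TestRanking:
    def test_dominant_feature_ranked_first(self):
        folds = [pd.Series({"a": 5.0, "b": 1.0, "c": 0.0}) for _ in range(10)]
        ranking = rank_features(folds)
        assert list(ranking.index)[0] == "a"

    def test_ties_broken_by_name_order(self):
        folds = [pd.Series({"b": 1.0, "a": 1.0, "c": 2.0})]
        ranking = rank_features(folds)
        assert list(ranking.index) == ["c", "a", "b"]

    def test_features_missing_in_some_folds_scored_zero(self):
        folds = [pd.Series({"a": 1.0}), pd.Series({"b": 3.0})]
        ranking = rank_features(folds)
        assert ranking["a"] == 1.0 and ranking["b"] == 3.0


class TestCompareClassifiers:
    def test_identical_arrays(self):
        arr = np.linspace(0.5, 0.9, 10)
        out = compare_classifiers({"a": arr, "b": arr.copy()})
        assert out["omnibus"]["H"] == 0.0 and out["omnibus"]["p"] == 1.0
        assert out["pairwise"]["a vs b"] == 1.0

    def test_large_shift_detected(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.6, 0.01, 10)
        out = compare_classifiers({"a": a, "b": a + 0.3})
        assert out["omnibus"]["p"] < 0.01

    def test_two_arrays_consistent_with_rank_sum(self):
        from scipy import stats

        rng = np.random.default_rng(1)
        a, b = rng.normal(0.6, 0.05, 10), rng.normal(0.7, 0.05, 10)
        out = compare_classifiers({"a": a, "b": b})
        # Kruskal-Wallis with 2 groups is the rank-sum test
        assert out["omnibus"]["p"] == pytest.approx(
            stats.ranksums(a, b).pvalue, rel=0.05)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            compare_classifiers({"a": np.ones(10), "b": np.ones(9)})


class TestNestedCVSmall:
    def test_reduced_folds_when_class_small(self):
        X, y, _ = _toy(n=16, p=10, sep=4.0)
        with pytest.warns(UserWarning, match="reducing outer"):
            ens, rep = nested_cv(X, y, ModelSpec("logreg", seed=0),
                                 n_outer=10, n_inner=3)
        assert len(ens.members) == 8

    def test_members_predict_prob_vectors(self):
        X, y, _ = _toy(n=40, p=10, sep=4.0)
        ens, rep = nested_cv(X, y, ModelSpec("logreg", seed=0),
                             n_outer=5, n_inner=4)
        p = soft_vote(ens, X)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)
        assert rep.val_accuracies.size == 5 and rep.test_accuracies.size == 5

    def test_tree_family_runs_end_to_end(self):
        X, y, informative = _toy(n=50, p=10, sep=4.0, seed=2)
        ens, rep = nested_cv(X, y, ModelSpec("gradient_boosted_trees", seed=0),
                             n_outer=3, n_inner=3, n_draws=2)
        assert len(ens.members) == 3
        assert all(set(m.params) == {"tree_depth", "l2_leaf_regularization",
                                     "bagging_temperature", "random_strength"}
                   for m in ens.members)
        assert rep.test_mean > 0.7
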