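"""Learners, native metrics and the subject-disjoint evaluation protocol."""

import numpy as np
import pytest

from eegdem import (
    ClassifierSpec,
    SMOTEConfig,
    auc,
    confusion,
    make_split,
    metrics,
    run_task,
    train_classifier,
)
from eegdem.classify import ConfusionCounts, KNNClassifier, build_model


class TestConfusion:
    def test_counts_one_miss_per_class(self):
        y = np.array([1] * 10 + [0] * 10)
        pred = y.copy()
        pred[0] = 0
        pred[10] = 1
        c = confusion(y, pred)
        assert (c.TP, c.FN, c.FP, c.TN) == (9, 1, 1, 9)

    def test_perfect_prediction(self):
        y = np.array([1, 0, 1, 0])
        c = confusion(y, y)
        assert c.FN == c.FP == 0 and c.total == 4

    def test_all_positive_prediction_on_balanced_truth(self):
        y = np.array([1] * 5 + [0] * 5)
        c = confusion(y, np.ones(10, dtype=int))
        assert c.TN == 0 and c.FP == 5

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])


class TestMetrics:
    def test_direct_arithmetic_example(self):
        m = metrics(ConfusionCounts(TP=9, FP=2, TN=8, FN=1))
        assert m["sensitivity"] == pytest.approx(0.900, abs=1e-4)
        assert m["precision"] == pytest.approx(0.8182, abs=1e-4)
        assert m["accuracy"] == pytest.approx(0.850, abs=1e-4)
        assert m["f1"] == pytest.approx(0.8571, abs=1e-4)

    def test_undefined_ratios_flagged_not_zero(self):
        m = metrics(ConfusionCounts(TP=0, FP=0, TN=5, FN=5))
        assert m["precision"] is None
        assert m["accuracy"] == 0.5

    def test_formulas_match_brute_force_on_random_counts(self, rng):
        for _ in range(50):
            tp, fp, tn, fn = rng.integers(1, 50, size=4)
            m = metrics(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
            assert m["sensitivity"] == tp / (tp + fn)
            assert m["precision"] == tp / (tp + fp)
            assert m["accuracy"] == (tp + tn) / (tp + fp + tn + fn)
            p, r = tp / (tp + fp), tp / (tp + fn)
            assert m["f1"] == pytest.approx(2 * p * r / (p + r), abs=1e-12)


def auc_pairwise_oracle(y, scores):
    """O(n^2) Mann-Whitney oracle: wins + half-ties over all pos/neg pairs."""
    pos = [s for yy, s in zip(y, scores) if yy == 1]
    neg = [s for yy, s in zip(y, scores) if yy == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_ranking(self):
        assert auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_constant_scores_give_half(self):
        assert auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    def test_single_class_flagged_undefined(self):
        assert auc([1, 1, 1], [0.1, 0.2, 0.3]) is None

    def test_matches_pairwise_oracle_on_random_instances(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 40))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            scores = np.round(rng.uniform(size=n), 2)  # rounding forces ties
            assert abs(auc(y, scores) - auc_pairwise_oracle(y, scores)) < 1e-12

    def test_matches_sklearn_reference(self, rng):
        from sklearn.metrics import roc_auc_score

        y = rng.integers(0, 2, size=200)
        y[0], y[1] = 0, 1
        scores = rng.normal(size=200)
        assert auc(y, scores) == pytest.approx(roc_auc_score(y, scores), abs=1e-12)


def blob_data(rng, n=100, sep=6.0):
    X = np.vstack(
        [rng.normal(0, 1, size=(n, 5)), rng.normal(sep, 1, size=(n, 5))]
    )
    y = np.array([0] * n + [1] * n)
    return X, y


class TestKNN:
    def test_separable_blobs_classified_perfectly(self, rng):
        X, y = blob_data(rng)
        model = KNNClassifier(n_neighbors=6).fit(X, y)
        Xt = np.vstack([rng.normal(0, 1, size=(20, 5)), rng.normal(6, 1, size=(20, 5))])
        yt = np.array([0] * 20 + [1] * 20)
        assert (model.predict(Xt) == yt).mean() == 1.0

    def test_tie_broken_toward_nearest_neighbour(self):
        # 3 negatives at distance ~1, 3 positives at distance ~2, nearest is negative
        X = np.array(
            [[1.0], [1.1], [1.2], [-2.0], [-2.1], [-2.2]]
        )
        y = np.array([0, 0, 0, 1, 1, 1])
        model = KNNClassifier(n_neighbors=6).fit(X, y)
        assert model.predict(np.array([[0.9]]))[0] == 0
        assert model.predict(np.array([[-1.9]]))[0] == 1

    def test_score_is_positive_neighbour_fraction(self):
        X = np.array([[0.0], [0.1], [0.2], [10.0], [10.1], [10.2]])
        y = np.array([1, 1, 1, 0, 0, 0])
        model = KNNClassifier(n_neighbors=3).fit(X, y)
        assert model.predict_score(np.array([[0.05]]))[0] == 1.0
        assert model.predict_score(np.array([[10.05]]))[0] == 0.0


class TestLearners:
    @pytest.mark.parametrize("learner", ["KNN", "RF", "XGB", "ET"])
    def test_deterministic_under_seed(self, learner, rng):
        X, y = blob_data(rng, n=60, sep=2.0)
        a = build_model(ClassifierSpec(learner), seed=7)
        b = build_model(ClassifierSpec(learner), seed=7)
        a.fit(X, y)
        b.fit(X, y)
        Xt = rng.normal(1, 2, size=(50, 5))
        assert np.array_equal(a.predict(Xt), b.predict(Xt))
        assert np.allclose(a.predict_score(Xt), b.predict_score(Xt))

    def test_hyperparameter_defaults_pinned(self):
        assert ClassifierSpec("KNN").hyperparameters["n_neighbors"] == 6
        assert ClassifierSpec("RF").hyperparameters["n_estimators"] == 120
        assert ClassifierSpec("RF").hyperparameters["min_samples_split"] == 28
        assert ClassifierSpec("XGB").hyperparameters["n_estimators"] == 280
        assert ClassifierSpec("XGB").hyperparameters["reg_alpha"] == 0.05
        assert ClassifierSpec("ET").hyperparameters["min_samples_leaf"] == 15

    def test_permuted_labels_yield_chance_cv_accuracy(self):
        accs = []
        for rep in range(20):
            rg = np.random.default_rng(rep)
            X, y = blob_data(rg, n=60, sep=2.0)
            y_perm = rg.permutation(y)
            model = build_model(ClassifierSpec("RF"), seed=rep)
            model.fit(X[:80], y_perm[:80])
            accs.append((model.predict(X[80:]) == y_perm[80:]).mean())
        assert np.mean(accs) == pytest.approx(0.5, abs=0.1)

    def test_single_class_training_rejected(self, small_svd_features):
        from eegdem import assemble_task

        table = assemble_task(small_svd_features, "AD-vs-HC")
        ad_only = table[table["group"] == "AD"]
        with pytest.raises(ValueError, match="single class"):
            train_classifier(ClassifierSpec("KNN"), ad_only, seed=0)


class TestRunTask:
    @pytest.fixture(scope="class")
    def task_setup(self, small_cohort):
        subjects = [
            (r.subject_id, r.group) for r in small_cohort if r.group in ("AD", "HC")
        ]
        return make_split(subjects, 0.2, n_folds=5, seed=4)

    def test_fold_metric_count_matches_plan(self, small_svd_features, task_setup):
        rep = run_task(
            small_svd_features, "AD-vs-HC", ClassifierSpec("KNN"), task_setup,
            SMOTEConfig(seed=4),
        )
        assert len(rep.fold_metrics) == 5

    def test_window_counts_conserved(self, small_svd_features, task_setup):
        rep = run_task(
            small_svd_features, "AD-vs-HC", ClassifierSpec("KNN"), task_setup,
            SMOTEConfig(seed=4),
        )
        table = small_svd_features[
            small_svd_features["subject_id"].isin(task_setup.test_subjects)
        ]
        for group in ("AD", "HC"):
            assert rep.window_counts[group] == (table["group"] == group).sum()
        assert rep.window_counts["total"] == len(table)

    def test_report_is_deterministic(self, small_svd_features, task_setup):
        args = (small_svd_features, "AD-vs-HC", ClassifierSpec("ET"), task_setup,
                SMOTEConfig(seed=4))
        assert run_task(*args).test_metrics == run_task(*args).test_metrics

    def test_window_level_cv_is_optimistic_against_subject_level(
        self, small_svd_features, task_setup
    ):
        """Row-stratified CV sees near-duplicate windows across folds, so its
        accuracy exceeds the leakage-free subject-held-out CV accuracy."""
        subj = run_task(
            small_svd_features, "AD-vs-HC", ClassifierSpec("KNN"), task_setup,
            SMOTEConfig(seed=4), cv_unit="subject",
        )
        win = run_task(
            small_svd_features, "AD-vs-HC", ClassifierSpec("KNN"), task_setup,
            SMOTEConfig(seed=4), cv_unit="window",
        )
        assert win.cv_mean["accuracy"] > subj.cv_mean["accuracy"]

    def test_unknown_cv_unit_rejected(self, small_svd_features, task_setup):
        with pytest.raises(ValueError, match="cv_unit"):
            run_task(
                small_svd_features, "AD-vs-HC", ClassifierSpec("KNN"), task_setup,
                SMOTEConfig(seed=4), cv_unit="fold",
            )
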