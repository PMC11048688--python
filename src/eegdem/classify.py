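"""Supervised classification and evaluation on windowed feature tables.

Four finalist learners — K-Nearest Neighbors, Random Forest, XGBoost and
Extra Trees — each fixed to the hyperparameters found by the original grid
search.  The tree ensembles are backed by scikit-learn / xgboost; KNN and the
whole metric suite (confusion counts, sensitivity, precision, accuracy, F1,
ROC AUC) are implemented natively.

Evaluation follows the subject-disjoint protocol: per-fold cross-validation
metrics on the SMOTE-balanced training portion, then final metrics on the
untouched (unbalanced) test windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .features import feature_columns
from .resampling import (
    SMOTEConfig,
    SplitPlan,
    SYNTHETIC_SUBJECT_ID,
    assemble_task,
    make_split,
    smote_oversample,
)

LEARNERS = ("KNN", "RF", "XGB", "ET")

#: Hyperparameters fixed by the study's grid search.
DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "KNN": {
        "leaf_size": 30,
        "metric": "euclidean",
        "n_neighbors": 6,
        "p": 2,
        "weights": "uniform",
    },
    "RF": {
        "criterion": "gini",
        "n_estimators": 120,
        "max_depth": None,
        "min_samples_split": 28,
        "min_samples_leaf": 10,
    },
    "XGB": {
        "learning_rate": 0.1,
        "n_estimators": 280,
        "max_depth": 8,
        "colsample_bytree": 1,
        "reg_alpha": 0.05,
    },
    "ET": {
        "criterion": "gini",
        "n_estimators": 150,
        "max_depth": None,
        "min_samples_split": 30,
        "min_samples_leaf": 15,
    },
}


@dataclass(frozen=True)
class ClassifierSpec:
    learner: str = "KNN"
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.learner not in LEARNERS:
            raise ValueError(f"unknown learner {self.learner!r}; expected {LEARNERS}")
        merged = {**DEFAULT_HYPERPARAMETERS[self.learner], **self.hyperparameters}
        object.__setattr__(self, "hyperparameters", merged)


class KNNClassifier:
    """Native k-nearest-neighbour classifier with uniform weights.

    With the study's even k=6 a 3-3 vote can tie; ties are broken toward the
    class of the single nearest neighbour, which is deterministic and local.
    The positive-class score is the fraction of positive neighbours.
    """

    def __init__(self, n_neighbors: int = 6, leaf_size: int = 30):
        self.n_neighbors = n_neighbors
        self.leaf_size = leaf_size

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KNNClassifier":
        from sklearn.neighbors import NearestNeighbors

        self._X = np.asarray(X, dtype=float)
        self._y = np.asarray(y, dtype=int)
        self._nn = NearestNeighbors(
            n_neighbors=min(self.n_neighbors, len(self._y)),
            leaf_size=self.leaf_size,
            metric="euclidean",
        ).fit(self._X)
        return self

    def _neighbor_labels(self, X: np.ndarray) -> np.ndarray:
        idx = self._nn.kneighbors(np.asarray(X, dtype=float), return_distance=False)
        return self._y[idx]  # neighbours come back sorted by distance

    def predict(self, X: np.ndarray) -> np.ndarray:
        labels = self._neighbor_labels(X)
        votes = labels.mean(axis=1)
        pred = (votes > 0.5).astype(int)
        tied = votes == 0.5
        pred[tied] = labels[tied, 0]  # nearest neighbour decides
        return pred

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        return self._neighbor_labels(X).mean(axis=1)


class _SklearnStyleModel:
    """Uniform handle over the ensemble learners: predict / score / importances."""

    def __init__(self, estimator, learner: str):
        self._est = estimator
        self.learner = learner

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_SklearnStyleModel":
        self._est.fit(X, y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self._est.predict(X), dtype=int)

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self._est.predict_proba(X)[:, 1], dtype=float)

    @property
    def feature_importances_(self) -> np.ndarray:
        return np.asarray(self._est.feature_importances_, dtype=float)


def build_model(spec: ClassifierSpec, seed: int):
    hp = spec.hyperparameters
    if spec.learner == "KNN":
        return KNNClassifier(n_neighbors=hp["n_neighbors"], leaf_size=hp["leaf_size"])
    if spec.learner == "RF":
        from sklearn.ensemble import RandomForestClassifier

        return _SklearnStyleModel(
            RandomForestClassifier(
                criterion=hp["criterion"],
                n_estimators=hp["n_estimators"],
                max_depth=hp["max_depth"],
                min_samples_split=hp["min_samples_split"],
                min_samples_leaf=hp["min_samples_leaf"],
                random_state=seed,
            ),
            "RF",
        )
    if spec.learner == "ET":
        from sklearn.ensemble import ExtraTreesClassifier

        return _SklearnStyleModel(
            ExtraTreesClassifier(
                criterion=hp["criterion"],
                n_estimators=hp["n_estimators"],
                max_depth=hp["max_depth"],
                min_samples_split=hp["min_samples_split"],
                min_samples_leaf=hp["min_samples_leaf"],
                random_state=seed,
            ),
            "ET",
        )
    if spec.learner == "XGB":
        from xgboost import XGBClassifier

        return _SklearnStyleModel(
            XGBClassifier(
                learning_rate=hp["learning_rate"],
                n_estimators=hp["n_estimators"],
                max_depth=hp["max_depth"],
                colsample_bytree=hp["colsample_bytree"],
                reg_alpha=hp["reg_alpha"],
                random_state=seed,
                n_jobs=1,
                verbosity=0,
            ),
            "XGB",
        )
    raise ValueError(spec.learner)


def train_classifier(spec: ClassifierSpec, train_rows: pd.DataFrame, seed: int):
    """Fit a learner on a labelled feature table; deterministic under seed."""
    cols = feature_columns(train_rows)
    X = train_rows[cols].to_numpy(dtype=float)
    y = train_rows["label"].to_numpy(dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training data contains a single class")
    if not np.all(np.isfinite(X)):
        raise ValueError("training features contain non-finite values")
    model = build_model(spec, seed)
    model.fit(X, y)
    return model


# ---------------------------------------------------------------------------
# metrics (native implementations)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal lengths")
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Sensitivity, precision, accuracy and F1; undefined ratios become None."""

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    sens = ratio(c.TP, c.TP + c.FN)
    prec = ratio(c.TP, c.TP + c.FP)
    acc = ratio(c.TP + c.TN, c.total)
    if prec is None or sens is None or (prec + sens) == 0:
        f1 = None
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return {"sensitivity": sens, "precision": prec, "accuracy": acc, "f1": f1}


def auc(y_true, scores) -> float | None:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Equals the probability that a random positive outranks a random negative,
    counting ties as half; None when only one class is present.
    """
    from scipy.stats import rankdata

    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(scores)  # midpoint convention for ties
    pos_rank_sum = float(ranks[y_true == 1].sum())
    return (pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


# ---------------------------------------------------------------------------
# task evaluation


@dataclass
class EvaluationReport:
    task: str
    learner: str
    seed: int
    fold_metrics: list[dict]
    cv_mean: dict
    test_metrics: dict
    per_class: dict
    window_counts: dict

    def to_dict(self) -> dict:
        return asdict(self)


def _evaluate(model, rows: pd.DataFrame) -> tuple[dict, ConfusionCounts, np.ndarray, np.ndarray]:
    cols = feature_columns(rows)
    X = rows[cols].to_numpy(dtype=float)
    y = rows["label"].to_numpy(dtype=int)
    pred = model.predict(X)
    scores = model.predict_score(X)
    c = confusion(y, pred)
    m = metrics(c)
    m["auc"] = auc(y, scores)
    return m, c, y, pred


def _nanmean(values: list[float | None]) -> float | None:
    vals = [v for v in values if v is not None]
    return float(np.mean(vals)) if vals else None


def run_task(
    features: pd.DataFrame,
    task: str,
    spec: ClassifierSpec,
    plan: SplitPlan,
    smote_cfg: SMOTEConfig,
    cv_unit: str = "subject",
) -> EvaluationReport:
    """Cross-validate on the training portion and test on the held-out subjects.

    SMOTE balances only the training rows of each fit; validation and test
    windows are left at their natural class proportions.

    ``cv_unit`` selects the cross-validation granularity.  ``"subject"``
    (default) holds out whole subjects per the plan's folds, so CV metrics
    are leakage-free like the test metrics.  ``"window"`` reproduces the
    historically common row-stratified 15-fold CV over the balanced training
    windows; with heavily overlapping windows its validation folds contain
    near-duplicates of fit rows, so its scores are optimistically biased —
    useful for studying exactly that bias, never for model assessment.
    """
    if cv_unit not in ("subject", "window"):
        raise ValueError(f"cv_unit must be 'subject' or 'window', got {cv_unit!r}")
    table = assemble_task(features, task)
    metric_keys = ("accuracy", "precision", "sensitivity", "f1", "auc")

    fold_metrics: list[dict] = []
    if cv_unit == "subject":
        for fold_index in sorted(plan.folds):
            held = set(plan.folds[fold_index])
            fit_subjects = plan.train_subjects - held
            fit_rows = table[table["subject_id"].isin(fit_subjects)]
            val_rows = table[table["subject_id"].isin(held)]
            if len(val_rows) == 0 or fit_rows["label"].nunique() < 2:
                fold_metrics.append({k: None for k in metric_keys} | {"fold": fold_index})
                continue
            fit_rows = smote_oversample(fit_rows, smote_cfg)
            model = train_classifier(spec, fit_rows, seed=plan.seed)
            m, _, _, _ = _evaluate(model, val_rows)
            fold_metrics.append({**m, "fold": fold_index})
    else:
        from sklearn.model_selection import StratifiedKFold

        balanced = smote_oversample(
            table[table["subject_id"].isin(plan.train_subjects)].reset_index(drop=True),
            smote_cfg,
        ).reset_index(drop=True)
        y_all = balanced["label"].to_numpy(dtype=int)
        skf = StratifiedKFold(n_splits=len(plan.folds) or 15, shuffle=True,
                              random_state=plan.seed)
        for fold_index, (fit_idx, val_idx) in enumerate(skf.split(y_all[:, None], y_all), 1):
            model = train_classifier(spec, balanced.iloc[fit_idx], seed=plan.seed)
            m, _, _, _ = _evaluate(model, balanced.iloc[val_idx])
            fold_metrics.append({**m, "fold": fold_index})

    cv_mean = {k: _nanmean([fm[k] for fm in fold_metrics]) for k in metric_keys}

    train_rows = table[table["subject_id"].isin(plan.train_subjects)]
    test_rows = table[table["subject_id"].isin(plan.test_subjects)]
    assert not set(train_rows["subject_id"]) & set(test_rows["subject_id"])
    train_rows = smote_oversample(train_rows, smote_cfg)
    assert SYNTHETIC_SUBJECT_ID not in set(test_rows["subject_id"])
    model = train_classifier(spec, train_rows, seed=plan.seed)
    test_metrics, c, y, pred = _evaluate(model, test_rows)

    # per-class view (each class in turn treated as positive), Table-2 style
    per_class: dict[str, dict] = {}
    counts: dict[str, int] = {}
    for group in sorted(test_rows["group"].unique()):
        is_g = (test_rows["group"] == group).to_numpy()
        label_g = int(test_rows.loc[is_g, "label"].iloc[0])
        yt = (y == label_g).astype(int)
        yp = (pred == label_g).astype(int)
        per_class[group] = metrics(confusion(yt, yp))
        counts[group] = int(is_g.sum())
    counts["total"] = int(len(test_rows))

    report = EvaluationReport(
        task=task,
        learner=spec.learner,
        seed=plan.seed,
        fold_metrics=fold_metrics,
        cv_mean=cv_mean,
        test_metrics=test_metrics,
        per_class=per_class,
        window_counts=counts,
    )
    report.model = model  # expose for importance analysis
    return report


def run_matrix(
    recordings,
    overlaps=(0.5, 0.9),
    measures=("svd", "hfd", "zcr", "dfa", "hjorth"),
    learners=LEARNERS,
    tasks=("AD-vs-HC", "FTD-vs-HC", "AD-vs-FTD"),
    seeds=(1, 2, 3, 4, 5),
    n_folds: int = 15,
    run_cv: bool = False,
) -> pd.DataFrame:
    """Mean +/- sd test metrics over seeds for every grid cell.

    Feature extraction is shared across seeds (only the split changes per
    seed).  CV inside every cell is optional — the grid summary mirrors the
    published tables, which report test-set metrics.
    """
    from .features import extract_cohort_features
    from .windowing import WindowSpec

    rows = []
    subjects = [(r.subject_id, r.group) for r in recordings]
    for overlap in overlaps:
        wspec = WindowSpec(window_length_s=1.0, overlap_fraction=overlap)
        for measure in measures:
            features = extract_cohort_features(recordings, wspec, measure)
            for task in tasks:
                pos, neg = task.split("-vs-")
                task_subjects = [(s, g) for s, g in subjects if g in (pos, neg)]
                for learner in learners:
                    per_seed = []
                    for seed in seeds:
                        plan = make_split(task_subjects, 0.20, n_folds, seed=seed)
                        if not run_cv:
                            plan = SplitPlan(
                                plan.train_subjects,
                                plan.test_subjects,
                                plan.seed,
                                {1: tuple(sorted(plan.train_subjects))},
                            )
                        rep = run_task(
                            features,
                            task,
                            ClassifierSpec(learner),
                            plan,
                            SMOTEConfig(seed=seed),
                        )
                        per_seed.append(rep.test_metrics)
                    row = {
                        "overlap": overlap,
                        "measure": measure,
                        "task": task,
                        "learner": learner,
                        "n_seeds": len(seeds),
                    }
                    for key in ("accuracy", "precision", "sensitivity", "f1", "auc"):
                        vals = [m[key] for m in per_seed if m[key] is not None]
                        row[f"{key}_mean"] = float(np.mean(vals)) if vals else None
                        row[f"{key}_sd"] = float(np.std(vals)) if vals else None
                    rows.append(row)
    return pd.DataFrame(rows)
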