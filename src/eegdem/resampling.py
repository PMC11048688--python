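"""Subject-disjoint splitting, subject-wise cross-validation folds, and SMOTE.

The central methodological safeguard of the analysis is that no subject
contributes windows to both the training and the test side: splitting and
fold assignment operate on subjects, never on windows.  SMOTE (synthetic
minority oversampling) is applied strictly after splitting, to training rows
only; synthetic rows carry a sentinel subject id so they can never leak into
a test set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import feature_columns

SYNTHETIC_SUBJECT_ID = "__smote__"

TASKS = {
    # task -> (positive group, negative group)
    "AD-vs-HC": ("AD", "HC"),
    "FTD-vs-HC": ("FTD", "HC"),
    "AD-vs-FTD": ("AD", "FTD"),
}


@dataclass(frozen=True)
class SplitPlan:
    """Subject-level 80:20 split plus cross-validation fold hold-outs."""

    train_subjects: frozenset[str]
    test_subjects: frozenset[str]
    seed: int
    folds: dict[int, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.train_subjects & self.test_subjects:
            raise ValueError("train and test subjects overlap")
        held = [s for fold in self.folds.values() for s in fold]
        if sorted(held) != sorted(self.train_subjects):
            raise ValueError("folds must partition the training subjects")

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "train_subjects": sorted(self.train_subjects),
                "test_subjects": sorted(self.test_subjects),
                "folds": {str(k): sorted(v) for k, v in self.folds.items()},
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SplitPlan":
        d = json.loads(text)
        return cls(
            train_subjects=frozenset(d["train_subjects"]),
            test_subjects=frozenset(d["test_subjects"]),
            seed=d["seed"],
            folds={int(k): tuple(v) for k, v in d["folds"].items()},
        )


@dataclass(frozen=True)
class SMOTEConfig:
    k_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def make_split(
    subjects: list[tuple[str, str]],
    test_fraction: float = 0.20,
    n_folds: int = 15,
    seed: int = 0,
) -> SplitPlan:
    """Group-stratified subject split plus round-robin fold assignment.

    The 80:20 rounding resolves ties toward the larger training set; folds
    hold out subjects (not rows), keeping the cross-validation subject-wise.
    """
    ids = [s for s, _ in subjects]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids")
    if len(ids) < n_folds + 2:
        raise ValueError(f"need >= {n_folds + 2} subjects for {n_folds} folds")

    rng = np.random.default_rng(seed)
    by_group: dict[str, list[str]] = {}
    for sid, group in subjects:
        by_group.setdefault(group, []).append(sid)
    if len(by_group) < 2:
        raise ValueError("need at least two groups to split")

    train: list[str] = []
    test: list[str] = []
    for group in sorted(by_group):
        members = sorted(by_group[group])
        perm = rng.permutation(len(members))
        n_test = int(np.floor(test_fraction * len(members)))  # ties -> train
        if n_test == 0 or n_test == len(members):
            raise ValueError(
                f"group {group!r} would be absent from train or test "
                f"({len(members)} subjects at test fraction {test_fraction})"
            )
        chosen = [members[i] for i in perm]
        test.extend(chosen[:n_test])
        train.extend(chosen[n_test:])

    # round-robin fold fill per class keeps folds roughly class-balanced
    folds: dict[int, list[str]] = {i: [] for i in range(1, n_folds + 1)}
    cursor = 0
    for group in sorted(by_group):
        members = [s for s in train if s in set(by_group[group])]
        for sid in rng.permutation(members):
            folds[cursor % n_folds + 1].append(str(sid))
            cursor += 1
    return SplitPlan(
        train_subjects=frozenset(train),
        test_subjects=frozenset(test),
        seed=seed,
        folds={k: tuple(v) for k, v in folds.items()},
    )


def assemble_task(features: pd.DataFrame, task: str) -> pd.DataFrame:
    """Filter a feature table to the task's two groups and attach binary labels.

    The disease group is the positive class; for AD-vs-FTD, AD is positive.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {sorted(TASKS)}")
    pos, neg = TASKS[task]
    present = set(features["group"].unique())
    for group in (pos, neg):
        if group not in present:
            raise ValueError(f"group {group!r} required for task {task} is missing")
    out = features[features["group"].isin([pos, neg])].copy()
    out["label"] = (out["group"] == pos).astype(int)
    return out.reset_index(drop=True)


def smote_oversample(features: pd.DataFrame, cfg: SMOTEConfig) -> pd.DataFrame:
    """Balance a two-class training table by interpolated minority rows.

    Each synthetic row is x + u * (x_nbr - x) with u ~ Uniform(0, 1), where
    x is a random minority row and x_nbr one of its k nearest minority
    neighbours (Euclidean distance over feature columns).  Synthetic rows are
    flagged (``is_synthetic``) and given a sentinel subject id.
    """
    if "label" not in features.columns:
        raise ValueError("expected a labelled task table (assemble_task output)")
    labels = features["label"].to_numpy()
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2:
        raise ValueError(f"SMOTE requires exactly two classes, got {classes.size}")

    out = features.copy()
    if "is_synthetic" not in out.columns:
        out["is_synthetic"] = False
    if counts[0] == counts[1]:
        return out.reset_index(drop=True)

    minority = classes[np.argmin(counts)]
    need = int(abs(counts[0] - counts[1]))
    cols = feature_columns(features)
    X_min = features.loc[labels == minority, cols].to_numpy(dtype=float)
    if X_min.shape[0] <= cfg.k_neighbors:
        raise ValueError(
            f"minority class has {X_min.shape[0]} rows; needs > k_neighbors="
            f"{cfg.k_neighbors}"
        )

    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=cfg.k_neighbors + 1).fit(X_min)
    neighbors = nn.kneighbors(X_min, return_distance=False)[:, 1:]  # drop self

    rng = np.random.default_rng(cfg.seed)
    base = rng.integers(0, X_min.shape[0], size=need)
    pick = rng.integers(0, cfg.k_neighbors, size=need)
    u = rng.uniform(0.0, 1.0, size=need)
    parents = neighbors[base, pick]
    X_new = X_min[base] + u[:, None] * (X_min[parents] - X_min[base])

    synth = pd.DataFrame(X_new, columns=cols)
    synth["subject_id"] = SYNTHETIC_SUBJECT_ID
    synth["group"] = features.loc[labels == minority, "group"].iloc[0]
    synth["window_index"] = -1
    synth["label"] = minority
    synth["is_synthetic"] = True
    return pd.concat([out, synth[out.columns]], ignore_index=True)
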