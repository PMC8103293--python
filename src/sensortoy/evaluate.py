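"""The classification experiment: bespoke stratified CV and fold-wise metrics.

The cohort is small and nearly balanced, so the cross-validation design is
minority-driven: the fold count equals the number of label-1 children, each
test fold holds exactly one child of each label, and when there are fewer
label-0 than label-1 children the first few (in seed-permuted order) label-0
children are reused in a second fold.  With 49 positives and 46 negatives
this gives 49 folds with 3 reused negatives.  Per-fold test sets have two
samples, so fold accuracy is 0, 0.5 or 1 and the paired structure carries
all the statistical information — every configuration in an analysis grid is
evaluated on the identical fold plan so fold-wise score differences are
meaningful for signed-rank comparison.

Four classifiers are compared: k-nearest neighbour, logistic regression,
decision tree, and a radial-kernel support vector machine, at conventional
default hyperparameters (exposed in :func:`classifier_specs`).  Scale-aware
models standardise features with statistics fitted on the training fold
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.neighbors import KNeighborsClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureSelector, design_matrix

CLASSIFIER_KINDS = ("knn", "logistic_regression", "decision_tree", "svm")

#: the 7 admissible roadrunner level subsets, canonical order
LEVEL_SUBSETS: tuple[frozenset[int], ...] = tuple(
    frozenset(s) for s in ({0}, {1}, {2}, {0, 1}, {0, 2}, {1, 2}, {0, 1, 2})
)

META_COLUMNS = ("id", "label", "levels", "game")


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str
    standardize: bool
    params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind: {self.kind}")


def classifier_specs() -> dict[str, ClassifierSpec]:
    """The four compared models with their documented default settings."""
    return {
        "knn": ClassifierSpec("knn", True, {"n_neighbors": 5}),
        "logistic_regression": ClassifierSpec("logistic_regression", True, {"C": 1.0}),
        "decision_tree": ClassifierSpec("decision_tree", False, {"criterion": "gini"}),
        "svm": ClassifierSpec("svm", True, {"kernel": "rbf", "C": 1.0}),
    }


def build_estimator(spec: ClassifierSpec, seed: int):
    params = dict(spec.params)
    if spec.kind == "knn":
        clf = KNeighborsClassifier(**params)
    elif spec.kind == "logistic_regression":
        clf = LogisticRegression(max_iter=1000, **params)
    elif spec.kind == "decision_tree":
        clf = DecisionTreeClassifier(random_state=seed, **params)
    else:
        clf = SVC(random_state=seed, **params)
    if spec.standardize:
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])
    return clf


@dataclass(frozen=True)
class FoldPlan:
    """Minority-driven stratified folds: one child per label in each test set."""

    folds: tuple[tuple[str, str], ...]      # (label-1 id, label-0 id) per fold
    reuse_ids: tuple[str, ...]              # label-0 ids appearing in two folds
    all_ids: tuple[str, ...]

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def train_ids(self, fold: int) -> tuple[str, ...]:
        test = set(self.folds[fold])
        return tuple(i for i in self.all_ids if i not in test)


def build_fold_plan(labels: Mapping[str, int], seed: int) -> FoldPlan:
    """One fold per label-1 child; surplus demand on label-0 met by reuse.

    With at least as many label-1 as label-0 children (the study's case,
    49/46) every label-0 child is tested at least once and the first
    ``#1 - #0`` of them, in seed-permuted order, exactly twice.  A cohort
    with surplus label-0 children still gets one fold per label-1 child;
    the leftover negatives then only ever serve as training data.
    """
    pos = sorted(i for i, y in labels.items() if y == 1)
    neg = sorted(i for i, y in labels.items() if y == 0)
    if not pos or not neg:
        raise ValueError("both labels must be present to build a fold plan")
    rng = np.random.default_rng(seed)
    pos = [pos[i] for i in rng.permutation(len(pos))]
    neg = [neg[i] for i in rng.permutation(len(neg))]
    folds = tuple((pos[k], neg[k % len(neg)]) for k in range(len(pos)))
    # negatives serving in more than one test set (all of them if the
    # positive surplus wraps the whole class)
    reuse = tuple(neg[: max(0, min(len(neg), len(pos) - len(neg)))])
    return FoldPlan(folds=folds, reuse_ids=reuse, all_ids=tuple(sorted(labels)))


@dataclass(frozen=True)
class RunResult:
    """Fold-wise scores of one (game, classifier, selector) configuration."""

    config: dict
    accuracy: np.ndarray
    f1: np.ndarray
    recall: np.ndarray

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracy))

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.f1))

    @property
    def mean_recall(self) -> float:
        return float(np.mean(self.recall))

    def scores(self, metric: str) -> np.ndarray:
        if metric not in ("accuracy", "f1", "recall"):
            raise ValueError(f"unknown metric: {metric}")
        return getattr(self, metric)


def _fold_scores(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    """Accuracy, F1 and recall of label 1 on a 2-sample test set (F1 -> 0 on 0/0)."""
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    acc = float(np.mean(y_true == y_pred))
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return acc, f1, recall


def evaluate_config(
    table: pd.DataFrame,
    spec: ClassifierSpec,
    plan: FoldPlan,
    seed: int,
    *,
    config: Optional[dict] = None,
) -> RunResult:
    """Fit/score one configuration over every fold of the shared plan.

    Feature columns are all non-metadata columns of the table, so the table
    itself (built with the wanted selector) decides the model input.
    """
    cols = [c for c in table.columns if c not in META_COLUMNS]
    missing = set(plan.all_ids) - set(table["id"])
    if missing:
        raise ValueError(f"feature table lacks planned children: {sorted(missing)[:5]}")
    indexed = table.set_index("id")
    X_all = indexed[cols].to_numpy(dtype=float)
    y_all = indexed["label"].to_numpy(dtype=int)
    loc = {i: k for k, i in enumerate(indexed.index)}

    acc = np.empty(plan.n_folds)
    f1 = np.empty(plan.n_folds)
    rec = np.empty(plan.n_folds)
    for k in range(plan.n_folds):
        test_idx = [loc[i] for i in plan.folds[k]]
        train_idx = [loc[i] for i in plan.train_ids(k)]
        fold_spec = spec
        if spec.kind == "knn" and spec.params.get("n_neighbors", 5) > len(train_idx):
            # tiny-cohort guard: k may not exceed the training-fold size
            fold_spec = ClassifierSpec("knn", spec.standardize,
                                       {**spec.params, "n_neighbors": len(train_idx)})
        est = build_estimator(fold_spec, seed)
        est.fit(X_all[train_idx], y_all[train_idx])
        pred = est.predict(X_all[test_idx])
        acc[k], f1[k], rec[k] = _fold_scores(y_all[test_idx], pred)
    return RunResult(config=dict(config or {"classifier": spec.kind}),
                     accuracy=acc, f1=f1, recall=rec)


def run_analysis_one(
    tables: Mapping[str, pd.DataFrame],
    seed: int,
    *,
    plan: Optional[FoldPlan] = None,
) -> tuple[dict[tuple[str, str], RunResult], FoldPlan]:
    """Grid 1: every classifier on the full feature table of each game.

    ``tables`` maps game name -> feature table (family=both, all levels).
    All 8 configurations share one fold plan, keyed ``(game, classifier)``.
    """
    first = next(iter(tables.values()))
    if plan is None:
        plan = build_fold_plan(dict(zip(first["id"], first["label"])), seed)
    grid: dict[tuple[str, str], RunResult] = {}
    for game, table in tables.items():
        for kind, spec in classifier_specs().items():
            grid[(game, kind)] = evaluate_config(
                table, spec, plan, seed,
                config={"game": game, "classifier": kind,
                        "levels": str(table["levels"].iloc[0]), "family": "both"},
            )
    return grid, plan


def run_analysis_two(
    subset_tables: Mapping[tuple[str, str], pd.DataFrame],
    best: ClassifierSpec,
    seed: int,
    *,
    plan: Optional[FoldPlan] = None,
) -> tuple[dict[tuple[str, str], RunResult], FoldPlan]:
    """Grid 2: the best classifier over level subsets x feature families.

    ``subset_tables`` maps (levels string, family) -> roadrunner feature
    table; the canonical grid is 7 subsets x 3 families, all on one plan.
    """
    first = next(iter(subset_tables.values()))
    if plan is None:
        plan = build_fold_plan(dict(zip(first["id"], first["label"])), seed)
    grid: dict[tuple[str, str], RunResult] = {}
    for (levels, family), table in subset_tables.items():
        grid[(levels, family)] = evaluate_config(
            table, best, plan, seed,
            config={"game": "roadrunner", "classifier": best.kind,
                    "levels": levels, "family": family},
        )
    return grid, plan


def selector_grid() -> list[FeatureSelector]:
    """The 21 selectors of the level/family analysis, canonical order."""
    return [FeatureSelector(levels, family)
            for levels in LEVEL_SUBSETS for family in ("sensor", "game", "both")]
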