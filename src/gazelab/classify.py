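"""Feature selection, classifiers and the repeated-subsampling harness.

The classification question is whether the 34 gaze/performance
features separate strong from weak performers.  Labels are binary:
``total_correct >= threshold`` (the weak-performer cut-off from
:mod:`gazelab.group_stats`) is *strong*, below is *weak*.

Three feature-selection strategies are provided:

* :func:`select_k_best` — univariate ranking (ANOVA F-score), keep the
  ``k`` highest-scoring features;
* :func:`select_l1` — features with nonzero coefficients of an
  L1-penalised logistic regression (the penalty strength ``C`` tunes
  the retained-subset size);
* :func:`select_tree_hierarchical` — features whose impurity-based
  importance in a tree ensemble reaches a threshold (default: the mean
  importance, so equal importances keep every feature).

Four classifiers (decision tree, random forest, extremely randomised
trees, AdaBoost) are evaluated with repeated random subsampling:
100 independent stratified 60/40 train/test splits, accuracy measured
on each test fold, the distribution of the 100 accuracies reported.
Accuracy distributions of two settings are compared with the
Mann-Whitney test from :mod:`gazelab.group_stats`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    RandomForestClassifier,
)
from sklearn.feature_selection import SelectKBest, f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score
from sklearn.model_selection import train_test_split
from sklearn.tree import DecisionTreeClassifier

from .group_stats import GroupComparison, mann_whitney_u

__all__ = [
    "EvaluationSpec",
    "AccuracyDistribution",
    "CLASSIFIERS",
    "make_classifier",
    "performance_labels",
    "select_k_best",
    "select_l1",
    "select_tree_hierarchical",
    "evaluate",
    "compare_accuracies",
]


@dataclass(frozen=True)
class EvaluationSpec:
    """Protocol of the repeated-subsampling evaluation."""

    n_iterations: int = 100
    train_fraction: float = 0.6
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class AccuracyDistribution:
    """Per-iteration test accuracies of one classifier/selector setting."""

    classifier: str
    selector: str
    accuracies: np.ndarray
    n_redraws: int = 0

    def __post_init__(self) -> None:
        self.accuracies = np.asarray(self.accuracies, dtype=float)
        if ((self.accuracies < 0) | (self.accuracies > 1)).any():
            raise ValueError("accuracies must lie in [0, 1]")

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd(self) -> float:
        return float(self.accuracies.std(ddof=1)) if len(self.accuracies) > 1 else 0.0

    def __repr__(self) -> str:
        return (
            f"AccuracyDistribution({self.classifier}/{self.selector}: "
            f"{self.mean:.2f} (+/-{self.sd:.2f}), n={len(self.accuracies)})"
        )


def performance_labels(total_correct: Sequence[float], threshold: int) -> np.ndarray:
    """Binary target: 1 = strong (total_correct >= threshold), 0 = weak."""
    return (np.asarray(total_correct, dtype=float) >= threshold).astype(int)


# ---------------------------------------------------------------------------
# feature selection — each returns the retained column names, order preserved


def _as_frame(features) -> pd.DataFrame:
    if isinstance(features, pd.DataFrame):
        return features
    return pd.DataFrame(np.asarray(features, dtype=float))


def select_k_best(features, labels, k: int) -> list:
    """Keep the ``k`` features with the highest ANOVA F-score."""
    X = _as_frame(features)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds the {X.shape[1]} available features")
    sel = SelectKBest(score_func=f_classif, k=k).fit(X.to_numpy(), np.asarray(labels))
    mask = sel.get_support()
    return [c for c, keep in zip(X.columns, mask) if keep]


def select_l1(features, labels, C: float = 0.1) -> list:
    """Features with nonzero coefficients under L1-penalised logistic
    regression.

    Features are standardised before fitting so the penalty treats
    scales evenly; smaller ``C`` (stronger penalty) retains fewer
    features.
    """
    X = _as_frame(features)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("L1 selection needs both classes present")
    arr = X.to_numpy(dtype=float)
    sd = arr.std(axis=0)
    sd[sd == 0] = 1.0
    arr = (arr - arr.mean(axis=0)) / sd
    model = LogisticRegression(
        l1_ratio=1.0, C=C, solver="liblinear", max_iter=2000, random_state=0
    ).fit(arr, y)
    mask = np.abs(model.coef_[0]) > 1e-10
    return [c for c, keep in zip(X.columns, mask) if keep]


def select_tree_hierarchical(
    features, labels, threshold: float | None = None, random_state: int = 0
) -> list:
    """Features whose ensemble importance reaches the threshold.

    Importances come from an extremely-randomised-trees fit; the
    default threshold is the mean importance and retention uses ``>=``,
    so a degenerate all-equal importance profile keeps all features.
    """
    X = _as_frame(features)
    y = np.asarray(labels)
    model = ExtraTreesClassifier(n_estimators=250, random_state=random_state).fit(
        X.to_numpy(dtype=float), y
    )
    imp = model.feature_importances_
    thr = float(imp.mean()) if threshold is None else float(threshold)
    return [c for c, v in zip(X.columns, imp) if v >= thr]


# ---------------------------------------------------------------------------
# classifiers

CLASSIFIERS = ("dt", "rf", "extra", "ada")


def make_classifier(name: str, random_state: int = 0):
    """Instantiate one of the four studied classifiers.

    Hyperparameters are the library defaults, fixed here: decision tree
    (``dt``), random forest (``rf``, 100 trees), extremely randomised
    trees (``extra``, 100 trees), AdaBoost (``ada``, 50 stumps with the
    SAMME algorithm).
    """
    if name == "dt":
        return DecisionTreeClassifier(random_state=random_state)
    if name == "rf":
        return RandomForestClassifier(random_state=random_state)
    if name == "extra":
        return ExtraTreesClassifier(random_state=random_state)
    if name == "ada":
        return AdaBoostClassifier(random_state=random_state)
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")


# ---------------------------------------------------------------------------
# evaluation harness


def evaluate(
    features,
    labels,
    classifier,
    spec: EvaluationSpec | None = None,
    selector: str = "all",
) -> AccuracyDistribution:
    """Repeated random subsampling evaluation of one classifier.

    Each of ``spec.n_iterations`` iterations draws an independent
    seeded train/test split at ``spec.train_fraction`` (stratified by
    default), fits a fresh clone of ``classifier`` on the training
    part and scores accuracy on the held-out part.  A split whose
    training part misses a class is re-drawn (counted in
    ``n_redraws``); with stratification this does not occur.

    ``classifier`` may be an estimator instance or one of the
    :data:`CLASSIFIERS` names.  The result is fully determined by
    ``spec.seed``.
    """
    spec = spec or EvaluationSpec()
    X = _as_frame(features).to_numpy(dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("evaluation needs at least two classes")
    if isinstance(classifier, str):
        name = classifier
        estimator = make_classifier(classifier, random_state=spec.seed)
    else:
        name = type(classifier).__name__
        estimator = classifier
    ss = np.random.SeedSequence(spec.seed)
    split_seeds = ss.generate_state(spec.n_iterations * 4)  # headroom for redraws
    accuracies = np.empty(spec.n_iterations)
    n_redraws = 0
    cursor = 0
    for it in range(spec.n_iterations):
        while True:
            rs = int(split_seeds[cursor] % (2**31 - 1))
            cursor += 1
            X_tr, X_te, y_tr, y_te = train_test_split(
                X,
                y,
                train_size=spec.train_fraction,
                random_state=rs,
                stratify=y if spec.stratified else None,
            )
            if len(np.unique(y_tr)) == len(classes):
                break
            n_redraws += 1
        model = clone(estimator)
        if hasattr(model, "random_state"):
            model.set_params(random_state=int(split_seeds[cursor - 1] % (2**31 - 1)))
        model.fit(X_tr, y_tr)
        accuracies[it] = accuracy_score(y_te, model.predict(X_te))
    return AccuracyDistribution(
        classifier=name, selector=selector, accuracies=accuracies, n_redraws=n_redraws
    )


def compare_accuracies(
    dist_a: AccuracyDistribution, dist_b: AccuracyDistribution
) -> GroupComparison:
    """Mann-Whitney comparison of two per-iteration accuracy vectors."""
    if len(dist_a.accuracies) != len(dist_b.accuracies):
        raise ValueError("accuracy distributions must have equal length")
    return mann_whitney_u(
        dist_a.accuracies,
        dist_b.accuracies,
        metric=f"{dist_a.classifier}/{dist_a.selector} vs {dist_b.classifier}/{dist_b.selector}",
    )
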