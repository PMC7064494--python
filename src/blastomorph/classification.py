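"""Five-classifier evaluation under stratified 10-fold cross-validation.

The classifier families compared are Gaussian naive Bayes, a ν-SVM
with RBF kernel (γ = 0.14), a small dense neural network (hidden
layers 30-30-30-10, ReLU, Adam, L2 = 1e-4), an unrestricted decision
tree and a 100-tree random forest.

By default the standardize+PCA reduction is fitted inside each
training fold and applied to the held-out fold, so no information from
test samples leaks into the preprocessing. ``pca_global=True`` instead
fits the reduction once on the whole table before splitting — the
optimistic variant some published pipelines use — and is provided for
comparison experiments.

The label-permutation control re-runs the identical evaluation after
shuffling outcome labels uniformly at random: chance-level metrics on
permuted labels indicate the pipeline does not manufacture signal.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import NuSVC, NuSVR
from sklearn.tree import DecisionTreeClassifier

from . import report
from .feature_pipeline import (DEFAULT_VARIANCE_THRESHOLD, FeatureTable,
                               apply_reduction, fit_reduction)
from .report import MetricSet, mean_metrics, metric_set

__all__ = [
    "FAMILIES",
    "ClassifierSpec",
    "CVResult",
    "default_classifier_specs",
    "stratified_folds",
    "cross_validate",
    "permutation_control",
    "select_best",
]

#: Family order also used as the final tie-break in model selection.
FAMILIES = ("naive_bayes", "nu_svm", "neural_net", "decision_tree",
            "random_forest")

_DEFAULT_HYPERPARAMETERS = {
    "naive_bayes": {},
    "nu_svm": {"nu": 0.5, "gamma": 0.14, "regression_mode": False},
    "neural_net": {"hidden_layer_sizes": (30, 30, 30, 10), "alpha": 1e-4,
                   "max_iter": 500},
    "decision_tree": {},
    "random_forest": {"n_estimators": 100},
}


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier family with its hyperparameters and seed."""

    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown family '{self.family}', expected one of {FAMILIES}")
        params = dict(_DEFAULT_HYPERPARAMETERS[self.family])
        params.update(self.hyperparameters)
        if self.family == "nu_svm":
            if not params["gamma"] > 0:
                raise ValueError("gamma must be positive")
            if not 0 < params["nu"] <= 1:
                raise ValueError("nu must lie in (0, 1]")
        if self.family == "random_forest" and params["n_estimators"] < 1:
            raise ValueError("random forest needs >= 1 tree")
        if self.family == "neural_net" and \
                min(params["hidden_layer_sizes"]) < 1:
            raise ValueError("hidden layer sizes must be positive")
        object.__setattr__(self, "hyperparameters", params)

    def build(self):
        """Instantiate the (seeded) scikit-learn estimator."""
        p = self.hyperparameters
        if self.family == "naive_bayes":
            # continuous PCA scores -> Gaussian likelihood per feature
            return GaussianNB()
        if self.family == "nu_svm":
            if p["regression_mode"]:
                return NuSVR(nu=p["nu"], kernel="rbf", gamma=p["gamma"])
            return NuSVC(nu=p["nu"], kernel="rbf", gamma=p["gamma"])
        if self.family == "neural_net":
            return MLPClassifier(
                hidden_layer_sizes=tuple(p["hidden_layer_sizes"]),
                activation="relu", solver="adam", alpha=p["alpha"],
                max_iter=p["max_iter"], random_state=self.seed,
            )
        if self.family == "decision_tree":
            return DecisionTreeClassifier(random_state=self.seed)
        return RandomForestClassifier(n_estimators=p["n_estimators"],
                                      random_state=self.seed)


def default_classifier_specs(seed: int = 0) -> list[ClassifierSpec]:
    return [ClassifierSpec(family=f, seed=seed) for f in FAMILIES]


@dataclass(frozen=True)
class CVResult:
    """Per-fold and fold-averaged metrics of one evaluated classifier."""

    per_fold: tuple[MetricSet, ...]
    averaged: MetricSet
    spec: ClassifierSpec
    fold_assignment: dict
    seed: int
    permuted: bool = False


def stratified_folds(labels: Sequence[int], k: int, seed: int) -> np.ndarray:
    """Assign samples to k stratified folds; returns an array of fold ids.

    Fold sizes differ by at most one, and each fold's positive count is
    within one of its proportional share. Deterministic for fixed seed.
    """
    y = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError(f"need k >= 2 folds, got {k}")
    counts = np.bincount(y, minlength=2)
    small = [c for c in counts if 0 < c < k]
    if counts.min() < k:
        raise ValueError(
            f"each class needs >= {k} members for {k}-fold stratification, "
            f"got class counts {counts.tolist()}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        assignment[test_idx] = fold
    return assignment


def _minmax_scale(X_train: np.ndarray, X_test: np.ndarray):
    """Scale design columns to [0, 1] by the training-fold range.

    The RBF bandwidth gamma = 0.14 is a sensible kernel width only for
    inputs of roughly unit range; raw PCA scores have variances equal
    to their eigenvalues, which would push the kernel into a degenerate
    (all-distances-huge) regime. Tree-based families are invariant to
    this monotone rescaling.
    """
    lo = X_train.min(axis=0)
    span = X_train.max(axis=0) - lo
    span[span == 0] = 1.0
    return (X_train - lo) / span, (X_test - lo) / span


def _fold_metrics(clf, X_train, y_train, X_test, y_test) -> MetricSet:
    if len(np.unique(y_train)) < 2:
        raise ValueError("degenerate fold: training set has a single class")
    with warnings.catch_warnings():
        warnings.filterwarnings("always", category=ConvergenceWarning)
        clf.fit(X_train, y_train)
    if isinstance(clf, NuSVR):
        scores = clf.predict(X_test)
        preds = (scores >= 0.5).astype(int)
    elif hasattr(clf, "decision_function"):
        scores = clf.decision_function(X_test)
        preds = clf.predict(X_test)
    else:
        scores = clf.predict_proba(X_test)[:, 1]
        preds = clf.predict(X_test)
    return metric_set(y_test, preds, scores)


def cross_validate(
    table: FeatureTable,
    spec: ClassifierSpec,
    k: int = 10,
    seed: int = 0,
    pca_global: bool = False,
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
    permuted: bool = False,
) -> CVResult:
    """Stratified k-fold evaluation of one classifier on a feature table.

    Each fold fits the standardize+PCA reduction and the classifier on
    the training samples only, predicts held-out labels and continuous
    scores, and computes the metric suite; the reported set is the
    arithmetic mean over folds.
    """
    y = table.label.to_numpy(dtype=int)
    folds = stratified_folds(y, k, seed)

    if pca_global:
        global_model = fit_reduction(table, variance_threshold)
        reduced_all = apply_reduction(global_model, table)
        design_all = reduced_all.drop(columns="label").to_numpy()

    per_fold = []
    for fold in range(k):
        test = np.flatnonzero(folds == fold)
        train = np.flatnonzero(folds != fold)
        if pca_global:
            X_train, X_test = design_all[train], design_all[test]
        else:
            model = fit_reduction(table.subset(train), variance_threshold)
            X_train = apply_reduction(model, table.subset(train)) \
                .drop(columns="label").to_numpy()
            X_test = apply_reduction(model, table.subset(test)) \
                .drop(columns="label").to_numpy()
        X_train, X_test = _minmax_scale(X_train, X_test)
        per_fold.append(_fold_metrics(spec.build(), X_train, y[train],
                                      X_test, y[test]))

    return CVResult(
        per_fold=tuple(per_fold),
        averaged=mean_metrics(per_fold),
        spec=spec,
        fold_assignment={sid: int(f) for sid, f in
                         zip(table.sample_ids, folds)},
        seed=seed,
        permuted=permuted,
    )


def permutation_control(
    table: FeatureTable,
    spec: ClassifierSpec,
    k: int = 10,
    seed: int = 0,
    permutation_seed: Optional[int] = None,
    pca_global: bool = False,
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD,
) -> CVResult:
    """Cross-validate after one uniform random permutation of the labels.

    The permuted label multiset equals the original, so class balance
    (and therefore fold stratification) is preserved. Chance-level
    averaged metrics here are the over-fitting control: any apparent
    skill on permuted labels would indicate leakage.
    """
    rng = np.random.default_rng(
        seed if permutation_seed is None else permutation_seed)
    permuted_labels = rng.permutation(table.label.to_numpy(dtype=int))
    return cross_validate(
        table.with_labels(permuted_labels), spec, k=k, seed=seed,
        pca_global=pca_global, variance_threshold=variance_threshold,
        permuted=True,
    )


def select_best(results: Sequence[CVResult]) -> CVResult:
    """Best result by averaged F1; ties broken by AUC, then family order."""
    results = list(results)
    if not results:
        raise ValueError("cannot select from an empty result list")
    return max(
        results,
        key=lambda r: (r.averaged.f1, r.averaged.auc,
                       -FAMILIES.index(r.spec.family)),
    )
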