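"""Stratified CV, the five classifier families, permutation control."""
import numpy as np
import pandas as pd
import pytest

import blastomorph as bm
from blastomorph.classification import (FAMILIES, ClassifierSpec, CVResult,
                                        cross_validate, permutation_control,
                                        select_best, stratified_folds)
from blastomorph.feature_pipeline import FeatureTable
from blastomorph.morphometry import FEATURE_NAMES
from blastomorph.report import MetricSet


class TestStratifiedFolds:
    def test_exact_divisibility_gives_exact_strata(self):
        labels = np.array([1] * 50 + [0] * 50)
        folds = stratified_folds(labels, 10, seed=0)
        for f in range(10):
            sel = folds == f
            assert sel.sum() == 10
            assert labels[sel].sum() == 5

    def test_cohort_like_counts_within_one_of_share(self):
        """134 samples, 71 positive, k=10: positives 7 or 8 per fold."""
        labels = np.array([1] * 71 + [0] * 63)
        folds = stratified_folds(labels, 10, seed=1)
        pos_per_fold = [labels[folds == f].sum() for f in range(10)]
        assert set(pos_per_fold) <= {7, 8}
        assert sum(pos_per_fold) == 71
        sizes = [(folds == f).sum() for f in range(10)]
        assert set(sizes) <= {13, 14}

    def test_partition_is_exact_and_deterministic(self):
        labels = np.random.default_rng(3).integers(0, 2, 97)
        a = stratified_folds(labels, 5, seed=42)
        b = stratified_folds(labels, 5, seed=42)
        np.testing.assert_array_equal(a, b)
        assert set(np.unique(a)) == set(range(5))
        assert len(a) == 97

    def test_small_class_is_an_error(self):
        labels = np.array([1] * 4 + [0] * 50)
        with pytest.raises(ValueError, match="class"):
            stratified_folds(labels, 10, seed=0)


def _toy_table(n=80, seed=0, separable=False):
    """Synthetic 24-feature table, optionally separable along pc_1.

    In the separable variant half the features load on a common bimodal
    factor that determines the label, so the leading principal
    component carries a wide-margin copy of the class signal.
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 24))
    if separable:
        labels = rng.integers(0, 2, n)
        factor = (2 * labels - 1) + 0.1 * rng.normal(size=n)
        X[:, :12] = np.outer(factor, rng.uniform(0.5, 2.0, 12)) \
            + 0.1 * rng.normal(size=(n, 12))
    else:
        labels = rng.integers(0, 2, n)
    return FeatureTable(
        features=pd.DataFrame(X, columns=list(FEATURE_NAMES)),
        age=pd.Series(rng.normal(34, 5, n)),
        label=pd.Series(labels),
        sample_ids=tuple(f"S{i}" for i in range(n)),
    )


class TestCrossValidate:
    def test_separable_labels_perfect_tree_f1(self):
        table = _toy_table(n=120, seed=4, separable=True)
        res = cross_validate(table, ClassifierSpec("decision_tree", seed=0),
                             k=10, seed=0)
        assert res.averaged.f1 == pytest.approx(1.0, abs=0.02)

    def test_random_labels_stay_at_chance(self):
        table = _toy_table(n=120, seed=5)
        res = cross_validate(table, ClassifierSpec("nu_svm", seed=0),
                             k=10, seed=0)
        assert 0.30 <= res.averaged.auc <= 0.70

    def test_all_families_run_and_average_per_fold(self, small_table):
        # small table (n=10) cannot support k=10; use k=2
        for family in FAMILIES:
            res = cross_validate(small_table, ClassifierSpec(family, seed=0),
                                 k=2, seed=0)
            assert len(res.per_fold) == 2
            for field in ("f1", "auc", "accuracy"):
                vals = [getattr(m, field) for m in res.per_fold]
                assert getattr(res.averaged, field) == \
                    pytest.approx(np.mean(vals))

    def test_fold_assignment_covers_all_samples(self):
        table = _toy_table(n=60, seed=6)
        res = cross_validate(table, ClassifierSpec("naive_bayes"), k=5, seed=1)
        assert set(res.fold_assignment) == set(table.sample_ids)
        assert set(res.fold_assignment.values()) == set(range(5))

    def test_fixed_seeds_fix_every_metric(self):
        table = _toy_table(n=60, seed=7)
        a = cross_validate(table, ClassifierSpec("random_forest", seed=3),
                           k=5, seed=3)
        b = cross_validate(table, ClassifierSpec("random_forest", seed=3),
                           k=5, seed=3)
        assert a.averaged == b.averaged
        assert a.per_fold == b.per_fold

    def test_pca_global_variant_runs(self):
        table = _toy_table(n=60, seed=8)
        res = cross_validate(table, ClassifierSpec("nu_svm"), k=5, seed=0,
                             pca_global=True)
        assert 0 <= res.averaged.auc <= 1

    def test_nu_svr_regression_mode(self):
        table = _toy_table(n=60, seed=9, separable=True)
        spec = ClassifierSpec("nu_svm",
                              hyperparameters={"regression_mode": True})
        res = cross_validate(table, spec, k=5, seed=0)
        assert res.averaged.auc > 0.8  # separable signal recovered


class TestPermutationControl:
    def test_flagged_and_deterministic(self):
        table = _toy_table(n=60, seed=10)
        a = permutation_control(table, ClassifierSpec("naive_bayes"),
                                k=5, seed=2, permutation_seed=9)
        b = permutation_control(table, ClassifierSpec("naive_bayes"),
                                k=5, seed=2, permutation_seed=9)
        assert a.permuted and len(a.per_fold) == 5
        assert a.averaged == b.averaged

    def test_destroys_real_signal(self):
        table = _toy_table(n=120, seed=11, separable=True)
        spec = ClassifierSpec("decision_tree", seed=0)
        real = cross_validate(table, spec, k=5, seed=0)
        permuted = [permutation_control(table, spec, k=5, seed=0,
                                        permutation_seed=s).averaged.auc
                    for s in range(5)]
        assert real.averaged.auc - np.mean(permuted) > 0.25


class TestSelectBest:
    @staticmethod
    def _result(family, f1, auc):
        m = MetricSet(sensitivity=0.5, specificity=0.5, precision=0.5,
                      accuracy=0.5, f1=f1, auc=auc, fpr=0.5, fnr=0.5)
        return CVResult(per_fold=(m,), averaged=m,
                        spec=ClassifierSpec(family),
                        fold_assignment={}, seed=0)

    def test_max_f1_wins(self):
        results = [self._result("naive_bayes", 0.71, 0.7),
                   self._result("nu_svm", 0.74, 0.7),
                   self._result("decision_tree", 0.60, 0.9)]
        assert select_best(results).spec.family == "nu_svm"

    def test_single_result_returned(self):
        r = self._result("random_forest", 0.5, 0.5)
        assert select_best([r]) is r

    def test_tie_broken_by_auc_then_family_order(self):
        a = self._result("neural_net", 0.7, 0.77)
        b = self._result("random_forest", 0.7, 0.75)
        assert select_best([a, b]) is a
        c = self._result("naive_bayes", 0.7, 0.77)
        assert select_best([a, c]).spec.family == "naive_bayes"

    def test_empty_list_is_an_error(self):
        with pytest.raises(ValueError):
            select_best([])


def test_classifier_spec_validation():
    with pytest.raises(ValueError):
        ClassifierSpec("nu_svm", hyperparameters={"gamma": -1})
    with pytest.raises(ValueError):
        ClassifierSpec("nu_svm", hyperparameters={"nu": 1.5})
    with pytest.raises(ValueError):
        ClassifierSpec("random_forest", hyperparameters={"n_estimators": 0})
    with pytest.raises(ValueError):
        ClassifierSpec("unknown_family")


def test_default_hyperparameters_are_the_published_settings():
    specs = {s.family: s for s in bm.default_classifier_specs(seed=1)}
    assert specs["nu_svm"].hyperparameters["gamma"] == 0.14
    assert specs["neural_net"].hyperparameters["hidden_layer_sizes"] == \
        (30, 30, 30, 10)
    assert specs["random_forest"].hyperparameters["n_estimators"] == 100
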