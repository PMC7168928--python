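"""Single-spectrum classifiers, cross-validation, diagnostic metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rodraman.classify import (DiagnosticReport, crossval_scores,
                               diagnostic_report, fit_linear_svm,
                               fit_logit_lda, fit_pca_lsvm, pca_reduce,
                               predicted_class)
from rodraman.synth import CLASS_NORMAL, CLASS_ROD


def separable_clouds(n_per_class=100, gap_sd=5.0, d=4, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=(n_per_class, d))
    b = rng.normal(gap_sd, 1.0, size=(n_per_class, d))
    X = np.vstack([a, b])
    y = np.array([CLASS_NORMAL] * n_per_class + [CLASS_ROD] * n_per_class)
    return X, y


class TestScoreContract:
    def test_threshold_one(self):
        assert predicted_class(1.5) == CLASS_ROD
        assert predicted_class(0.5) == CLASS_NORMAL
        # tie rule: exactly 1 is called normal
        assert predicted_class(1.0) == CLASS_NORMAL

    def test_scores_positive_and_consistent_with_counts(self):
        X, y = separable_clouds(seed=4)
        scored = crossval_scores(X, y, k=5, seed=0)
        assert all(s.score > 0 for s in scored)
        rep = diagnostic_report(scored)
        n_pred_rod = sum(1 for s in scored if predicted_class(s.score) == CLASS_ROD)
        assert rep.tp + rep.fp == n_pred_rod


class TestLdaLogit:
    def test_separable_limit(self):
        X, y = separable_clouds()
        scored = crossval_scores(X, y, fitter=fit_logit_lda, k=10, seed=1)
        assert diagnostic_report(scored).accuracy >= 0.99

    def test_permutation_null_accuracy_near_chance(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(400, 4))
        y = np.array([CLASS_NORMAL, CLASS_ROD] * 200)
        rng.shuffle(y)
        scored = crossval_scores(X, y, fitter=fit_logit_lda, k=10, seed=2)
        acc = diagnostic_report(scored).accuracy
        se = math.sqrt(0.25 / 400)
        assert abs(acc - 0.5) <= 3 * se + 0.01

    def test_both_classes_required(self):
        X = np.zeros((20, 4))
        y = np.array([CLASS_NORMAL] * 20)
        with pytest.raises(ValueError, match="both classes"):
            fit_logit_lda(X, y)


class TestCrossval:
    def test_every_spectrum_scored_once_in_equal_folds(self):
        X, y = separable_clouds(n_per_class=50)
        scored = crossval_scores(X, y, k=10, seed=0)
        assert len(scored) == 100
        assert len({s.spectrum_id for s in scored}) == 100
        fold_sizes = np.bincount([s.fold_index for s in scored])
        assert list(fold_sizes) == [10] * 10

    def test_same_seed_same_scores(self):
        X, y = separable_clouds(gap_sd=1.0, seed=5)
        a = crossval_scores(X, y, k=10, seed=3)
        b = crossval_scores(X, y, k=10, seed=3)
        assert [(s.spectrum_id, s.score, s.fold_index) for s in a] == \
            [(s.spectrum_id, s.score, s.fold_index) for s in b]

    def test_k2_and_k10_agree_on_separable_data(self):
        X, y = separable_clouds()
        for k in (2, 10):
            scored = crossval_scores(X, y, k=k, seed=0)
            assert diagnostic_report(scored).accuracy >= 0.99

    def test_grouped_mode_keeps_samples_together(self):
        X, y = separable_clouds(n_per_class=40)
        sample_ids = ([f"n{i % 3}" for i in range(40)]
                      + [f"r{i % 4}" for i in range(40)])
        scored = crossval_scores(X, y, k=7, seed=0, sample_ids=sample_ids,
                                 grouped=True)
        by_sample = {}
        for s in scored:
            by_sample.setdefault(s.sample_id, set()).add(s.fold_index)
        assert all(len(folds) == 1 for folds in by_sample.values())

    def test_rich_fold_request_is_restratified_with_warning(self):
        X, y = separable_clouds(n_per_class=5)
        with pytest.warns(UserWarning, match="re-stratified"):
            scored = crossval_scores(X, y, k=10, seed=0)
        assert len(scored) == 10


class TestPca:
    def test_rank_one_data(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=30)
        X = np.outer(rng.normal(size=50), v)
        Z, pca = pca_reduce(X, n_components=5)
        assert pca.explained_variance_ratio_[0] >= 0.999

    def test_reconstruction_error_monotone_in_components(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 30))
        errs = []
        for n in (2, 5, 10, 20):
            Z, pca = pca_reduce(X, n_components=n)
            rec = pca.inverse_transform(Z)
            errs.append(np.linalg.norm(X - rec))
        assert all(a >= b for a, b in zip(errs, errs[1:]))

    def test_train_mean_projects_to_origin(self):
        rng = np.random.default_rng(2)
        X = rng.normal(loc=3.0, size=(40, 10))
        _, pca = pca_reduce(X, n_components=3)
        np.testing.assert_allclose(pca.transform(X.mean(axis=0)[None, :]),
                                   0.0, atol=1e-10)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError, match="n_components"):
            pca_reduce(np.zeros((5, 3)), n_components=10)


class TestLinearSvm:
    def test_separable_limit(self):
        X, y = separable_clouds()
        scored = crossval_scores(X, y, fitter=fit_linear_svm, k=10, seed=0)
        assert diagnostic_report(scored).accuracy >= 0.99

    def test_duplicated_feature_column_does_not_change_accuracy(self):
        X, y = separable_clouds(gap_sd=2.0, seed=9)
        Xdup = np.hstack([X, X[:, :1]])
        a = diagnostic_report(crossval_scores(X, y, fitter=fit_linear_svm,
                                              k=5, seed=0)).accuracy
        b = diagnostic_report(crossval_scores(Xdup, y, fitter=fit_linear_svm,
                                              k=5, seed=0)).accuracy
        assert abs(a - b) <= 0.01

    def test_pca_lsvm_pipeline_on_separable_data(self):
        X, y = separable_clouds(n_per_class=80, d=50)
        scored = crossval_scores(
            X, y, fitter=lambda Xt, yt: fit_pca_lsvm(Xt, yt, n_components=10),
            k=5, seed=0)
        assert diagnostic_report(scored).accuracy >= 0.99


class TestDiagnosticReport:
    def test_reference_single_spectrum_counts(self):
        # the reference confusion matrix for single-spectrum classification;
        # only the cells consistent with their own counts are asserted (the
        # reference table's precision/NPV/FNR/specificity cells are not)
        rep = DiagnosticReport(tp=70470, fp=11205, fn=19530, tn=56295)
        assert round(100 * rep.accuracy, 1) == 80.5
        assert round(100 * rep.sensitivity, 1) == 78.3
        assert round(100 * rep.fpr, 1) == 16.6
        assert round(100 * rep.prevalence, 2) == 57.14

    def test_all_correct(self):
        rep = DiagnosticReport(tp=10, fp=0, fn=0, tn=10)
        assert rep.accuracy == 1.0 and rep.fpr == 0.0 and rep.fnr == 0.0

    def test_symmetric_quarters(self):
        rep = DiagnosticReport(tp=25, fp=25, fn=25, tn=25)
        assert rep.accuracy == rep.sensitivity == rep.specificity == 0.5

    def test_undefined_metric_is_nan_not_zero(self):
        rep = DiagnosticReport(tp=0, fp=0, fn=5, tn=5)
        assert math.isnan(rep.precision) and math.isnan(rep.fdr)

    @settings(deadline=None, derandomize=True)
    @given(st.tuples(st.integers(0, 10_000), st.integers(0, 10_000),
                     st.integers(0, 10_000), st.integers(0, 10_000)))
    def test_metric_identities(self, counts):
        tp, fp, fn, tn = counts
        if tp + fn == 0 or fp + tn == 0:
            return
        rep = DiagnosticReport(tp=tp, fp=fp, fn=fn, tn=tn)
        assert rep.sensitivity == pytest.approx(tp / (tp + fn))
        assert rep.specificity == pytest.approx(tn / (fp + tn))
        assert rep.fpr == pytest.approx(1 - rep.specificity)
        assert rep.fnr == pytest.approx(1 - rep.sensitivity)
        assert rep.accuracy == pytest.approx((tp + tn) / rep.total)
        if tp + fp > 0:
            assert rep.fdr == pytest.approx(1 - rep.precision)
        if tn + fn > 0:
            assert rep.for_rate == pytest.approx(1 - rep.npv)
        for name in ("prevalence", "accuracy", "sensitivity", "specificity"):
            assert 0.0 <= getattr(rep, name) <= 1.0
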