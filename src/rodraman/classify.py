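"""Single-spectrum supervised classification with odds-scale scores.

Two routes, both linear and both emitting the same score:

* ``fit_logit_lda`` — linear discriminant on the four biomarker ratios, with
  the discriminant output mapped through the logistic link to a posterior
  probability and then to odds P(ROD)/(1-P(ROD));
* ``pca_reduce`` + ``fit_linear_svm`` — full-spectrum route: project the
  preprocessed spectra onto the top 20 principal components (fitted on
  training folds only) and score with a linear support vector machine whose
  decision values are logistically calibrated on the training fold.

The shared odds scale makes aggregation classifier-agnostic: a score above 1
predicts ROD, below 1 normal. A score of exactly 1 is called normal — the
conservative choice for a measure-zero event. Evaluation is k-fold
cross-validation (default 10), stratified by class and randomized by
spectrum; a grouped (leave-samples-together) mode is available because
spectrum-wise folding lets the classifier see every patient during training.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GroupKFold, StratifiedKFold
from sklearn.svm import LinearSVC

from .biomarkers import BIOMARKER_NAMES
from .synth import CLASS_NORMAL, CLASS_ROD

__all__ = [
    "ScoredSpectrum",
    "DiagnosticReport",
    "fit_logit_lda",
    "fit_linear_svm",
    "fit_pca_lsvm",
    "pca_reduce",
    "crossval_scores",
    "crossval_table",
    "diagnostic_report",
    "predicted_class",
]

_PROB_CLIP = 1e-12
_ODDS_THRESHOLD = 1.0


@dataclass(frozen=True)
class ScoredSpectrum:
    """One spectrum's cross-validated odds score."""

    spectrum_id: str
    sample_id: str
    true_class: str
    score: float          # odds scale, > 0
    fold_index: int

    @property
    def predicted_class(self) -> str:
        return predicted_class(self.score)


def predicted_class(score: float) -> str:
    """Odds score -> class label; score above 1 predicts ROD, 1 or below
    predicts normal (tie goes to normal)."""
    return CLASS_ROD if score > _ODDS_THRESHOLD else CLASS_NORMAL


def _metric(num: float, den: float) -> float:
    """Ratio metric; an empty denominator yields NaN, never a fake zero."""
    return num / den if den > 0 else math.nan


@dataclass(frozen=True)
class DiagnosticReport:
    """Confusion counts plus the ten standard diagnostic metrics.

    ROD is the condition-positive class throughout. Counts may live on the
    probability scale (summing to 1) for closed-form reports. Metrics with an
    undefined denominator are NaN.
    """

    tp: float
    fp: float
    fn: float
    tn: float

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def prevalence(self) -> float:
        return _metric(self.tp + self.fn, self.total)

    @property
    def accuracy(self) -> float:
        return _metric(self.tp + self.tn, self.total)

    @property
    def sensitivity(self) -> float:
        return _metric(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return _metric(self.tn, self.fp + self.tn)

    @property
    def precision(self) -> float:
        return _metric(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return _metric(self.tn, self.tn + self.fn)

    @property
    def fdr(self) -> float:
        return 1.0 - self.precision

    @property
    def for_rate(self) -> float:
        return 1.0 - self.npv

    @property
    def fpr(self) -> float:
        return 1.0 - self.specificity

    @property
    def fnr(self) -> float:
        return 1.0 - self.sensitivity

    def to_dict(self, percent: bool = False) -> dict[str, float]:
        d = {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "prevalence": self.prevalence, "accuracy": self.accuracy,
            "precision": self.precision, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "fdr": self.fdr,
            "for_rate": self.for_rate, "npv": self.npv,
            "fpr": self.fpr, "fnr": self.fnr,
        }
        if percent:
            for k in list(d):
                if k not in ("tp", "fp", "fn", "tn"):
                    d[k] = round(100.0 * d[k], 1)
        return d


Scorer = Callable[[np.ndarray], np.ndarray]


def _to_odds(prob_rod: np.ndarray) -> np.ndarray:
    p = np.clip(prob_rod, _PROB_CLIP, 1.0 - _PROB_CLIP)
    return p / (1.0 - p)


def _check_classes(y: np.ndarray) -> None:
    present = set(np.unique(y))
    if not {CLASS_NORMAL, CLASS_ROD} <= present:
        raise ValueError(f"both classes required for fitting; got {sorted(present)}")


def fit_logit_lda(X: np.ndarray, y: Sequence[str]) -> Scorer:
    """Linear discriminant on the biomarker features, returning an odds scorer.

    The discriminant posterior (logistic in the linear discriminant output)
    gives P(ROD | x); the scorer returns the odds. A singular within-class
    covariance raises with a remediation hint.
    """
    y = np.asarray(y)
    _check_classes(y)
    lda = LinearDiscriminantAnalysis(solver="svd")
    with warnings.catch_warnings():
        warnings.filterwarnings("error", message="Variables are collinear")
        try:
            lda.fit(X, y)
        except Warning as w:  # pragma: no cover - defensive
            raise np.linalg.LinAlgError(
                "singular within-class covariance; jitter the features or "
                "drop collinear columns"
            ) from w
    rod_col = int(np.where(lda.classes_ == CLASS_ROD)[0][0])

    def scorer(Xn: np.ndarray) -> np.ndarray:
        return _to_odds(lda.predict_proba(Xn)[:, rod_col])

    return scorer


def pca_reduce(X: np.ndarray, n_components: int = 20) -> tuple[np.ndarray, PCA]:
    """Mean-centered projection onto the leading principal components.

    Returns the reduced matrix and the fitted basis, which must be reused to
    project held-out folds (fit on training data only).
    """
    n_comp_max = min(X.shape[0], X.shape[1])
    if n_components > n_comp_max:
        raise ValueError(
            f"n_components={n_components} exceeds the data rank bound {n_comp_max}"
        )
    pca = PCA(n_components=n_components, svd_solver="auto", random_state=0)
    Z = pca.fit_transform(X)
    return Z, pca


def fit_linear_svm(X: np.ndarray, y: Sequence[str], max_iter: int = 20000) -> Scorer:
    """Linear SVM with logistic score calibration on the training data.

    The SVM decision values are mapped through a one-dimensional logistic
    regression (Platt scaling) fitted on the same training fold, landing on
    the common odds scale with threshold 1.
    """
    y = np.asarray(y)
    _check_classes(y)
    svm = LinearSVC(C=1.0, max_iter=max_iter)
    with warnings.catch_warnings():
        warnings.filterwarnings("error", category=UserWarning,
                                message=".*did not converge.*")
        try:
            svm.fit(X, y)
        except UserWarning as w:
            raise RuntimeError(
                f"linear SVM failed to converge within max_iter={max_iter}"
            ) from w
    d_train = svm.decision_function(X).reshape(-1, 1)
    platt = LogisticRegression(C=1e6)
    platt.fit(d_train, y)
    rod_col = int(np.where(platt.classes_ == CLASS_ROD)[0][0])

    def scorer(Xn: np.ndarray) -> np.ndarray:
        d = svm.decision_function(Xn).reshape(-1, 1)
        return _to_odds(platt.predict_proba(d)[:, rod_col])

    return scorer


def fit_pca_lsvm(X: np.ndarray, y: Sequence[str], n_components: int = 20) -> Scorer:
    """Full-spectrum route: PCA to ``n_components`` then linear SVM, both
    fitted on the training fold only."""
    Z, pca = pca_reduce(X, n_components=n_components)
    svm_scorer = fit_linear_svm(Z, y)

    def scorer(Xn: np.ndarray) -> np.ndarray:
        return svm_scorer(pca.transform(Xn))

    return scorer


def crossval_scores(
    X: np.ndarray,
    y: Sequence[str],
    fitter: Callable[[np.ndarray, np.ndarray], Scorer] = fit_logit_lda,
    k: int = 10,
    seed: int = 0,
    spectrum_ids: Sequence[str] | None = None,
    sample_ids: Sequence[str] | None = None,
    grouped: bool = False,
) -> list[ScoredSpectrum]:
    """Score every spectrum exactly once by k-fold cross-validation.

    Folds are stratified by class and shuffled by ``seed`` (the default,
    spectrum-wise scheme). ``grouped=True`` keeps all spectra of one sample in
    the same fold (GroupKFold on ``sample_ids``), eliminating patient-identity
    leakage at the cost of very coarse folds in small cohorts.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_classes(y)
    n = X.shape[0]
    if spectrum_ids is None:
        spectrum_ids = [f"s{i}" for i in range(n)]
    if sample_ids is None:
        sample_ids = ["unknown"] * n
    if k < 2:
        raise ValueError("k must be >= 2")
    min_class = min(np.sum(y == CLASS_NORMAL), np.sum(y == CLASS_ROD))
    if grouped:
        k_eff = min(k, len(set(sample_ids)))
        splits = GroupKFold(n_splits=k_eff).split(X, y, groups=np.asarray(sample_ids))
    else:
        k_eff = min(k, int(min_class))
        if k_eff < k:
            warnings.warn(
                f"re-stratified to {k_eff} folds so every training split "
                f"contains both classes", stacklevel=2)
        splits = StratifiedKFold(n_splits=k_eff, shuffle=True,
                                 random_state=seed).split(X, y)
    scored: list[ScoredSpectrum] = []
    for fold, (tr, te) in enumerate(splits):
        scorer = fitter(X[tr], y[tr])
        s = scorer(X[te])
        for i, idx in enumerate(te):
            scored.append(ScoredSpectrum(
                spectrum_id=str(spectrum_ids[idx]),
                sample_id=str(sample_ids[idx]),
                true_class=str(y[idx]),
                score=float(s[i]),
                fold_index=fold,
            ))
    return scored


def crossval_table(
    features: pd.DataFrame,
    fitter: Callable[[np.ndarray, np.ndarray], Scorer] = fit_logit_lda,
    feature_columns: Sequence[str] = BIOMARKER_NAMES,
    **kwargs,
) -> list[ScoredSpectrum]:
    """``crossval_scores`` on a feature table with ``class`` /
    ``sample_id`` / ``spectrum_id`` columns."""
    missing = [c for c in list(feature_columns) + ["class"]
               if c not in features.columns]
    if missing:
        raise ValueError(f"feature table missing required columns: {missing}")
    return crossval_scores(
        features[list(feature_columns)].to_numpy(),
        features["class"].to_numpy(),
        fitter=fitter,
        spectrum_ids=features.get("spectrum_id"),
        sample_ids=features.get("sample_id"),
        **kwargs,
    )


def diagnostic_report(scored: Sequence[ScoredSpectrum]) -> DiagnosticReport:
    """Confusion counts from cross-validated scores (ROD = positive)."""
    if not scored:
        raise ValueError("no scored spectra")
    tp = fp = fn = tn = 0
    for s in scored:
        pred = predicted_class(s.score)
        if s.true_class == CLASS_ROD:
            if pred == CLASS_ROD:
                tp += 1
            else:
                fn += 1
        else:
            if pred == CLASS_ROD:
                fp += 1
            else:
                tn += 1
    if tp + fn == 0 or fp + tn == 0:
        raise ValueError("need at least one spectrum of each condition")
    return DiagnosticReport(tp=tp, fp=fp, fn=fn, tn=tn)
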