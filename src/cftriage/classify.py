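"""High/low tumor-fraction prediction from copy-number and size features.

A logistic regression with stratified 5-fold cross-validation predicts
whether a sample's mVAF is >= 10% from any subset of {genome-wide Z,
short/long fragment ratio, window fractions}. Out-of-fold predicted
probabilities are pooled into a single ROC curve; feature sets are
compared on identical fold assignments so AUC differences are paired.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from cftriage.errors import ConfigurationError, DomainError

log = logging.getLogger(__name__)

#: ridge fallback strength when the unpenalized fit fails to converge
#: (complete separation); small penalty, fixed, logged when used.
RIDGE_FALLBACK_C = 1000.0


def validate_feature_matrix(fm: pd.DataFrame, label_col: str = "high_tf") -> None:
    """Contract checks for a feature matrix: no NaN, binary label, >=2 per class."""
    if label_col not in fm.columns:
        raise ConfigurationError(f"label column {label_col!r} missing")
    if fm.isna().any().any():
        bad = fm.columns[fm.isna().any()].tolist()
        raise ConfigurationError(f"missing values in columns {bad}")
    y = fm[label_col].astype(int)
    counts = y.value_counts()
    if set(counts.index) != {0, 1} or (counts < 2).any():
        raise ConfigurationError("label must contain >= 2 samples in each of two classes")


def roc_auc(scores, labels) -> tuple[pd.DataFrame, float]:
    """Empirical ROC points and AUC via the rank (Mann-Whitney) statistic.

    Ties between a positive and a negative score contribute 1/2; the value
    is identical to the trapezoidal area under the empirical ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DomainError("ROC needs both classes present")
    ranks = rankdata(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    tps = np.cumsum(sorted_labels)
    fps = np.cumsum(1 - sorted_labels)
    # collapse threshold ties: keep the last point of each distinct score
    last_of_tie = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tpr = np.r_[0.0, tps[last_of_tie] / n_pos]
    fpr = np.r_[0.0, fps[last_of_tie] / n_neg]
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    return roc, float(auc)


@dataclass
class CVResult:
    """Pooled out-of-fold evaluation of one feature set."""

    name: str
    oof_scores: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)
    fold_assignment: np.ndarray = field(repr=False)
    roc: pd.DataFrame = field(repr=False)
    auc: float = 0.0
    seed: int = 0


class HighTumorFractionClassifier(BaseEstimator, ClassifierMixin):
    """Logistic regression (standardized features) for the mVAF >= 10% label.

    Maximum-likelihood fit (``penalty=None``); on non-convergence — which
    with these features means quasi-complete separation — the model refits
    with a fixed small ridge penalty and logs the fallback.

    Fitted attributes: ``pipeline_``, ``classes_``, ``used_ridge_``.
    """

    def __init__(self, max_iter: int = 1000, random_state: int | None = None):
        self.max_iter = max_iter
        self.random_state = random_state

    def _make(self, penalized: bool):
        lr = LogisticRegression(
            penalty="l2" if penalized else None,
            C=RIDGE_FALLBACK_C if penalized else 1.0,
            max_iter=self.max_iter,
            solver="lbfgs",
            random_state=self.random_state,
        )
        return make_pipeline(StandardScaler(), lr)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ConfigurationError("X must be 2-D with one row per label")
        self.used_ridge_ = False
        pipe = self._make(penalized=False)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            pipe.fit(X, y)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            log.info("unpenalized logistic fit did not converge; ridge fallback (C=%g)", RIDGE_FALLBACK_C)
            self.used_ridge_ = True
            pipe = self._make(penalized=True)
            pipe.fit(X, y)
        self.pipeline_ = pipe
        self.classes_ = pipe.classes_
        return self

    def predict_proba(self, X):
        return self.pipeline_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X):
        return self.pipeline_.predict(np.asarray(X, dtype=float))

    def decision_function(self, X):
        return self.pipeline_.decision_function(np.asarray(X, dtype=float))


def _fold_assignment(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(y), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        folds[test_idx] = f
    return folds


def fit_logistic_cv(
    fm: pd.DataFrame,
    features: list[str] | None = None,
    label_col: str = "high_tf",
    k: int = 5,
    seed: int = 0,
    folds: np.ndarray | None = None,
    name: str | None = None,
) -> CVResult:
    """Stratified k-fold CV of the logistic model; pooled out-of-fold scores.

    Standardization is fit on the training folds only (inside the
    pipeline), so no information leaks into the held-out fold. Every
    sample is scored exactly once out-of-fold; the pooled scores define
    the ROC/AUC.
    """
    validate_feature_matrix(fm, label_col)
    if features is None:
        features = [c for c in fm.columns if c != label_col]
    missing = [c for c in features if c not in fm.columns]
    if missing:
        raise ConfigurationError(f"unknown feature columns {missing}")
    if not features:
        raise ConfigurationError("empty feature set")
    X = fm[features].to_numpy(dtype=float)
    y = fm[label_col].to_numpy(dtype=int)
    if folds is None:
        folds = _fold_assignment(y, k, seed)
    oof = np.full(len(y), np.nan)
    for f in np.unique(folds):
        train, test = folds != f, folds == f
        if len(np.unique(y[train])) < 2:
            raise ConfigurationError(f"fold {f}: a class is absent from the training split")
        clf = HighTumorFractionClassifier(random_state=seed).fit(X[train], y[train])
        oof[test] = clf.predict_proba(X[test])[:, 1]
    roc, auc = roc_auc(oof, y)
    return CVResult(
        name=name or "+".join(features),
        oof_scores=oof,
        labels=y,
        fold_assignment=folds,
        roc=roc,
        auc=auc,
        seed=seed,
    )


def compare_feature_sets(
    fm: pd.DataFrame,
    sets: dict[str, list[str]],
    label_col: str = "high_tf",
    k: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, CVResult]]:
    """Paired AUC comparison: every feature set shares one fold assignment."""
    validate_feature_matrix(fm, label_col)
    y = fm[label_col].to_numpy(dtype=int)
    folds = _fold_assignment(y, k, seed)
    results = {}
    rows = []
    for set_name, features in sets.items():
        res = fit_logistic_cv(
            fm, features, label_col=label_col, k=k, seed=seed, folds=folds, name=set_name
        )
        results[set_name] = res
        rows.append({"feature_set": set_name, "features": ",".join(features), "auc": res.auc})
    return pd.DataFrame(rows), results
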