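"""Crop classifiers: one-vs-one cubic-polynomial SVM and bagged trees.

Both estimators follow the scikit-learn protocol (``fit``/``predict``,
``get_params``, fitted attributes with trailing underscores) and accept the
descriptor matrix of an assembled training table.

The SVM uses the raw inner-product polynomial kernel

    k(x, x_i) = (x^T x_i + 1)^3

(no kernel-scale normalisation; descriptor standardisation provides the
scaling) and aggregates the class-pair machines by vote count, with ties
broken by the summed signed decision values per class and finally by class
order.  The bagged ensemble grows 100 fully grown classification trees on
bootstrap resamples and votes.
"""

from __future__ import annotations

from typing import Optional

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import BaggingClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .accuracy import confusion, kappa, overall_accuracy

__all__ = ["PolySVMClassifier", "BaggedTreesClassifier", "cross_validate",
           "save_model", "load_model", "make_classifier"]


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D descriptor matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("descriptor matrix contains non-finite values")
    return X


class _StandardizedClassifier(ClassifierMixin, BaseEstimator):
    """Shared per-descriptor standardisation (fit on training data only)."""

    def _fit_scaler(self, X: np.ndarray, standardize: bool) -> np.ndarray:
        if standardize:
            self.mean_ = X.mean(axis=0)
            sd = X.std(axis=0)
            # constant descriptors carry no information; leave them centred
            self.scale_ = np.where(sd > 0, sd, 1.0)
        else:
            self.mean_ = np.zeros(X.shape[1])
            self.scale_ = np.ones(X.shape[1])
        self.n_features_in_ = X.shape[1]
        return (X - self.mean_) / self.scale_

    def _apply_scaler(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"record length {X.shape[1]} does not match the "
                f"{self.n_features_in_} descriptors seen during training")
        return (X - self.mean_) / self.scale_


class PolySVMClassifier(_StandardizedClassifier):
    """Multiclass SVM with cubic polynomial kernel, one machine per class pair.

    Parameters
    ----------
    C : float, default 1.0
        Box constraint of each binary machine.
    degree : int, default 3
        Polynomial order d of the kernel (x^T x_i + coef0)^d.
    coef0 : float, default 1.0
        Additive kernel offset c.
    standardize : bool, default True
        Standardise descriptors to zero mean / unit variance using the
        training data only.
    """

    def __init__(self, C: float = 1.0, degree: int = 3, coef0: float = 1.0,
                 standardize: bool = True):
        self.C = C
        self.degree = degree
        self.coef0 = coef0
        self.standardize = standardize

    def fit(self, X, y) -> "PolySVMClassifier":
        X = _as_matrix(X)
        y = np.asarray(y)
        if len(y) != len(X):
            raise ValueError("X and y have different lengths")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training table must contain at least 2 classes")
        Xs = self._fit_scaler(X, self.standardize)
        self.machines_: dict[tuple[int, int], SVC] = {}
        for a in range(len(self.classes_)):
            for b in range(a + 1, len(self.classes_)):
                mask = np.isin(y, self.classes_[[a, b]])
                ybin = (y[mask] == self.classes_[b]).astype(int)
                svc = SVC(C=self.C, kernel="poly", degree=self.degree,
                          gamma=1.0, coef0=self.coef0)
                svc.fit(Xs[mask], ybin)
                self.machines_[(a, b)] = svc
        return self

    def _votes_scores(self, Xs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n, k = len(Xs), len(self.classes_)
        votes = np.zeros((n, k), dtype=int)
        scores = np.zeros((n, k), dtype=float)
        for (a, b), svc in self.machines_.items():
            # decision > 0 favours class b (encoded 1 in the binary machine)
            d = svc.decision_function(Xs)
            win_b = d > 0
            votes[:, b] += win_b
            votes[:, a] += ~win_b
            scores[:, b] += d
            scores[:, a] -= d
        return votes, scores

    def decision_function(self, X) -> np.ndarray:
        """Per-class summed signed pairwise decision values."""
        check_is_fitted(self, "machines_")
        return self._votes_scores(self._apply_scaler(_as_matrix(X)))[1]

    def predict(self, X) -> np.ndarray:
        """Vote-count winner; ties fall back to summed decision values, then
        to class order."""
        check_is_fitted(self, "machines_")
        votes, scores = self._votes_scores(self._apply_scaler(_as_matrix(X)))
        n, k = votes.shape
        out = np.empty(n, dtype=self.classes_.dtype)
        for i in range(n):
            best = np.flatnonzero(votes[i] == votes[i].max())
            if len(best) > 1:
                s = scores[i, best]
                best = best[np.flatnonzero(s == s.max())]
            out[i] = self.classes_[best[0]]
        return out


class BaggedTreesClassifier(_StandardizedClassifier):
    """Bootstrap-aggregated ensemble of fully grown classification trees.

    100 trees by default, each trained on a bootstrap resample of the
    records; prediction is by majority vote.  Standardisation is kept for
    interface parity with the SVM (trees are scale invariant).
    """

    def __init__(self, n_estimators: int = 100, standardize: bool = True,
                 random_state: Optional[int] = None):
        self.n_estimators = n_estimators
        self.standardize = standardize
        self.random_state = random_state

    def fit(self, X, y) -> "BaggedTreesClassifier":
        X = _as_matrix(X)
        y = np.asarray(y)
        if len(y) != len(X):
            raise ValueError("X and y have different lengths")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training table must contain at least 2 classes")
        Xs = self._fit_scaler(X, self.standardize)
        self.ensemble_ = BaggingClassifier(
            estimator=DecisionTreeClassifier(),
            n_estimators=self.n_estimators, bootstrap=True,
            random_state=self.random_state)
        self.ensemble_.fit(Xs, y)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "ensemble_")
        return self.ensemble_.predict(self._apply_scaler(_as_matrix(X)))

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "ensemble_")
        return self.ensemble_.predict_proba(self._apply_scaler(_as_matrix(X)))


def make_classifier(algorithm: str, seed: Optional[int] = None, **kwargs):
    """Factory: ``svm_cubic`` or ``bagged_trees`` with default settings."""
    if algorithm == "svm_cubic":
        return PolySVMClassifier(**kwargs)
    if algorithm == "bagged_trees":
        return BaggedTreesClassifier(random_state=seed, **kwargs)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def cross_validate(model, X, y, folds: int = 5, seed: Optional[int] = 0) -> dict:
    """Stratified k-fold cross-validation pooled into one confusion matrix.

    Returns per-fold overall accuracy and kappa plus the pooled confusion
    matrix, pooled OA and pooled kappa over all held-out folds.
    """
    X = _as_matrix(X)
    y = np.asarray(y)
    if folds > len(y):
        raise ValueError("more folds than records")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    vocab = np.unique(y)
    pooled_truth, pooled_pred = [], []
    fold_oa, fold_kappa = [], []
    for train_idx, test_idx in skf.split(X, y):
        est = clone(model)
        est.fit(X[train_idx], y[train_idx])
        pred = est.predict(X[test_idx])
        cm = confusion(y[test_idx], pred, vocab)
        fold_oa.append(overall_accuracy(cm))
        fold_kappa.append(kappa(cm))
        pooled_truth.append(y[test_idx])
        pooled_pred.append(pred)
    pooled_cm = confusion(np.concatenate(pooled_truth),
                          np.concatenate(pooled_pred), vocab)
    return {
        "fold_overall_accuracy": fold_oa,
        "fold_kappa": fold_kappa,
        "confusion": pooled_cm,
        "overall_accuracy": overall_accuracy(pooled_cm),
        "kappa": kappa(pooled_cm),
    }


_FORMAT = "croptime-model"
_FORMAT_VERSION = 1


def save_model(model, path, feature_names: Optional[list[str]] = None) -> None:
    """Persist a fitted classifier to a self-describing versioned file."""
    payload = {
        "format": _FORMAT,
        "format_version": _FORMAT_VERSION,
        "class": type(model).__name__,
        "params": model.get_params(),
        "feature_names": feature_names,
        "model": model,
    }
    joblib.dump(payload, path)


def load_model(path):
    """Load a model saved by :func:`save_model`; predictions round-trip exactly."""
    payload = joblib.load(path)
    if payload.get("format") != _FORMAT:
        raise ValueError(f"{path} is not a {_FORMAT} file")
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format version "
                         f"{payload.get('format_version')}")
    return payload["model"]
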