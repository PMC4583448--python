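"""Two-class base classifiers with a uniform train/predict contract.

Four kinds are supported — linear discriminant analysis (``lda``), quadratic
discriminant analysis (``qda``), Gaussian naive Bayes (``nb``) and a linear
soft-margin support vector machine (``svm``) — each usable on a marker pair
(ensemble mode) or on all markers at once (traditional single-classifier
mode).  The discriminant models estimate class priors from training-fold
proportions; the SVM uses C = 1 by default.

Predictions are deterministic and never abstain.  A point falling exactly on
the decision boundary (equal posteriors / SVM score 0) is labelled +1
(periodontitis) by convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

KINDS = ("lda", "qda", "nb", "svm")


class DegenerateFoldError(ValueError):
    """Training fold lacks two members of each class."""


@dataclass
class TrainedClassifier:
    kind: str
    estimator: object
    feature_indices: tuple[int, ...]


def labels_from_scores(scores: np.ndarray) -> np.ndarray:
    """Signed decision scores -> labels; the boundary (score 0) goes to +1."""
    return np.where(np.asarray(scores) >= 0, 1, -1)


def check_training_fold(y: np.ndarray) -> None:
    y = np.asarray(y)
    for lab in (-1, 1):
        count = int((y == lab).sum())
        if count < 2:
            raise DegenerateFoldError(
                f"class {lab:+d} has {count} training sample(s); need >= 2 "
                "to estimate class statistics"
            )


def train(
    kind: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    feature_indices: tuple[int, ...] | None = None,
    *,
    svm_c: float = 1.0,
    qda_reg: float = 1e-4,
    nb_var_smoothing: float = 1e-9,
) -> TrainedClassifier:
    """Fit one base classifier on a (samples x features) training fold.

    ``feature_indices`` records which marker columns of the full matrix the
    fold was sliced from; it defaults to ``0..d-1``.

    QDA covariance shrinkage starts at ``qda_reg`` and escalates tenfold
    (up to 1) if the per-class covariance is still numerically singular.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown classifier kind {kind!r}; expected one of {KINDS}")
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X_train must be 2-D with one row per training label")
    check_training_fold(y)
    if feature_indices is None:
        feature_indices = tuple(range(X.shape[1]))
    elif len(feature_indices) != X.shape[1]:
        raise ValueError("feature_indices length must match X_train column count")

    if kind == "lda":
        est = LinearDiscriminantAnalysis(solver="svd")
        est.fit(X, y)
    elif kind == "qda":
        reg = qda_reg
        while True:
            est = QuadraticDiscriminantAnalysis(reg_param=reg)
            try:
                est.fit(X, y)
                break
            except np.linalg.LinAlgError:
                reg *= 10
                if reg > 1.0:
                    raise
    elif kind == "nb":
        est = GaussianNB(var_smoothing=nb_var_smoothing)
        est.fit(X, y)
    else:  # svm
        est = SVC(kernel="linear", C=svm_c)
        est.fit(X, y)
    return TrainedClassifier(kind=kind, estimator=est, feature_indices=feature_indices)


def decision_scores(clf: TrainedClassifier, X_test: np.ndarray) -> np.ndarray:
    """Signed score per test sample; positive leans periodontitis (+1)."""
    X = np.asarray(X_test, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != len(clf.feature_indices):
        raise ValueError(
            f"dimension mismatch: classifier expects {len(clf.feature_indices)} "
            f"feature(s), got {X.shape[1]}"
        )
    est = clf.estimator
    if clf.kind == "nb":
        logp = est.predict_log_proba(X)
        pos = int(np.argwhere(est.classes_ == 1)[0][0])
        return logp[:, pos] - logp[:, 1 - pos]
    scores = np.asarray(est.decision_function(X))
    # classes_ is sorted ascending, so positive scores already favour +1
    return scores


def predict(clf: TrainedClassifier, X_test: np.ndarray) -> np.ndarray:
    """Deterministic {−1, +1} labels (boundary ties resolved to +1)."""
    return labels_from_scores(decision_scores(clf, X_test))
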