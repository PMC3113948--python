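"""Window classifiers: LDA and Gaussian-kernel SVM in OVO / OVR modes.

LDA is the parameter-free baseline; the two SVM modes decompose the
multiclass problem one-vs-one (pairwise decisions fused by vote) or
one-vs-rest (class maximizing the discriminant function).  Features are
z-scored with statistics from the training fold only; the scaler lives
inside the sklearn pipeline so no test-fold information can leak into
the fit.

SVM hyperparameters (C, gamma) are either given explicitly or, with
``hyperparams="auto"``, selected by cross-validated grid search on the
training fold (C in 10^-1..10^3, gamma in 10^-3..10^1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

CLASSIFIER_KINDS = ("lda", "svm_ovo", "svm_ovr")


class DegenerateTrainingError(ValueError):
    """Training data contains fewer than two classes."""


@dataclass(frozen=True)
class ClassifierSpec:
    """Classifier configuration.

    ``hyperparams`` is either a ``(C, gamma)`` pair (gamma may be the
    sklearn string "scale") or the string "auto" for an internal
    cross-validated grid search.  LDA ignores hyperparameters entirely.
    """

    kind: str = "lda"
    kernel: str = "gaussian"
    hyperparams: tuple | str = (10.0, "scale")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.kind != "lda" and self.kernel != "gaussian":
            raise ValueError("only the Gaussian (RBF) kernel is supported")


def build_estimator(spec: ClassifierSpec):
    """Unfitted sklearn estimator (scaler + classifier) for ``spec``."""
    if spec.kind == "lda":
        clf = LinearDiscriminantAnalysis()
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])

    if spec.hyperparams == "auto":
        svc = SVC(kernel="rbf", random_state=spec.seed)
        pipe = Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", svc if spec.kind == "svm_ovo" else OneVsRestClassifier(svc)),
            ]
        )
        prefix = "clf__" if spec.kind == "svm_ovo" else "clf__estimator__"
        grid = {
            prefix + "C": np.logspace(-1, 3, 5),
            prefix + "gamma": np.logspace(-3, 1, 5),
        }
        cv = StratifiedKFold(5, shuffle=True, random_state=spec.seed)
        return GridSearchCV(pipe, grid, cv=cv, n_jobs=1)

    C, gamma = spec.hyperparams
    svc = SVC(kernel="rbf", C=C, gamma=gamma, random_state=spec.seed)
    if spec.kind == "svm_ovr":
        # explicit one-vs-rest: each class against the 8 others pooled,
        # final label = argmax of the per-class discriminant functions
        clf = OneVsRestClassifier(svc)
    else:
        # SVC is natively one-vs-one: pairwise decisions fused by vote,
        # ties broken by the aggregated pairwise decision values
        clf = svc
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


@dataclass
class TrainedModel:
    """Fitted classifier plus its spec and the labels it can emit."""

    spec: ClassifierSpec
    estimator: object
    class_labels: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        n_expected = self.estimator.n_features_in_
        if X.shape[1] != n_expected:
            raise ValueError(
                f"feature dimension {X.shape[1]} != training dimension {n_expected}"
            )
        return self.estimator.predict(X)


def train(X: np.ndarray, y: np.ndarray, spec: ClassifierSpec) -> TrainedModel:
    """Fit ``spec`` on a feature matrix; deterministic given ``spec.seed``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    classes = np.unique(y)
    if classes.size < 2:
        raise DegenerateTrainingError("training data must contain >= 2 classes")
    est = clone(build_estimator(spec))
    est.fit(X, y)
    return TrainedModel(spec=spec, estimator=est, class_labels=classes)


def predict(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    return model.predict(X)
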