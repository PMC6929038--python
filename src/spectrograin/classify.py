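"""The five benchmark classifiers behind one fit/predict contract.

Short names and default parameters:

* ``bayes`` — naive Bayes with per-feature Gaussian kernel density estimates
  (normal-reference bandwidth).
* ``svm``   — support vector machine, quadratic kernel, box constraint 1,
  one-vs-one multiclass.
* ``knn``   — k-nearest neighbours, 10 neighbours, Euclidean, equal weights.
* ``el``    — random subspace ensemble of 30 linear discriminants on
  40-dimensional feature subsets (majority vote).
* ``ann``   — one-hidden-layer backpropagation network, 10 tanh units.

``svm``/``knn``/``ann`` standardise features with training statistics inside
their pipeline. Also provides the stratified 3:1 split and the stratified
5-fold cross-validation protocol with pooled confusion matrices.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .dataset import SpectrumSet
from .exceptions import InvalidArgumentError, StratificationError

__all__ = [
    "ClassifierSpec",
    "EvalResult",
    "KernelDensityNaiveBayes",
    "RandomSubspaceEnsemble",
    "make_classifier",
    "fit_predict",
    "cross_validate",
    "stratified_split",
    "CLASSIFIER_NAMES",
]

logger = logging.getLogger(__name__)

CLASSIFIER_NAMES = ("bayes", "svm", "knn", "el", "ann")

#: Default parameter maps per classifier. The subspace ensemble's
#: ``learning_rate`` is recorded for provenance but inert under majority
#: voting (no boosting stage uses it).
DEFAULT_PARAMS: dict[str, dict] = {
    "bayes": {"kernel": "gaussian"},
    "svm": {"kernel": "quadratic", "box_constraint": 1.0, "multiclass": "one-vs-one"},
    "knn": {"n_neighbors": 10, "metric": "euclidean", "weights": "equal"},
    "el": {
        "method": "subspace",
        "n_learners": 30,
        "learning_rate": 0.1,
        "subspace_dim": 40,
    },
    "ann": {"type": "backpropagation", "n_hidden": 10, "max_epochs": 500},
}


@dataclass
class ClassifierSpec:
    """A named classifier plus its parameter map; fully determines a fit."""

    name: str
    params: dict = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise InvalidArgumentError(
                f"unknown classifier {self.name!r}; choose from {CLASSIFIER_NAMES}"
            )
        merged = dict(DEFAULT_PARAMS[self.name])
        merged.update(self.params)
        self.params = merged
        for key, val in self.params.items():
            if isinstance(val, (int, float)) and not isinstance(val, bool):
                if val <= 0:
                    raise InvalidArgumentError(
                        f"{self.name}: parameter {key} must be positive, got {val}"
                    )


@dataclass
class EvalResult:
    """Accuracies plus the pooled cross-validation confusion matrix."""

    train_accuracy: float
    test_accuracy: float
    cv_accuracy: float
    confusion: np.ndarray
    per_class_recall: np.ndarray
    classes: np.ndarray

    def __post_init__(self) -> None:
        for name in ("train_accuracy", "test_accuracy", "cv_accuracy"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise InvalidArgumentError(f"{name} = {v} outside [0, 1]")


class KernelDensityNaiveBayes(ClassifierMixin, BaseEstimator):
    """Naive Bayes with per-feature Gaussian kernel density class likelihoods.

    Each feature's class-conditional density is a Gaussian-kernel estimate
    over that class's training values with the normal-reference bandwidth
    ``1.06 * sd * n^(-1/5)`` (floored to a small positive value for constant
    features); class priors are the training frequencies.
    """

    def __init__(self, bandwidth_factor: float = 1.06):
        self.bandwidth_factor = bandwidth_factor

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, counts = np.unique(y, return_counts=True)
        if self.classes_.size < 2:
            raise InvalidArgumentError("need at least 2 classes")
        self.priors_ = counts / counts.sum()
        scale_floor = max(float(X.std()) * 1e-3, 1e-9)
        self._train_values = []
        self._bandwidths = []
        for c in self.classes_:
            V = X[y == c]
            sd = V.std(axis=0, ddof=1) if V.shape[0] > 1 else np.zeros(V.shape[1])
            h = self.bandwidth_factor * sd * V.shape[0] ** (-1 / 5)
            h = np.where(h > 0, h, scale_floor)
            self._train_values.append(V)
            self._bandwidths.append(h)
        self.n_features_in_ = X.shape[1]
        return self

    def _joint_log_likelihood(self, X: np.ndarray) -> np.ndarray:
        n = X.shape[0]
        out = np.empty((n, self.classes_.size))
        for ci in range(self.classes_.size):
            V = self._train_values[ci]  # (n_c, F)
            h = self._bandwidths[ci]  # (F,)
            # chunk test rows to bound the (n, n_c, F) intermediate
            chunk = max(1, int(2e7 // max(V.size, 1)))
            norm = np.log(V.shape[0]) + np.log(h) + 0.5 * np.log(2 * np.pi)
            for lo in range(0, n, chunk):
                hi = min(lo + chunk, n)
                z = (X[lo:hi, None, :] - V[None, :, :]) / h
                feat_ll = logsumexp(-0.5 * z**2, axis=1) - norm
                out[lo:hi, ci] = feat_ll.sum(axis=1)
        return out + np.log(self.priors_)

    def predict(self, X):
        check_is_fitted(self, "classes_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise InvalidArgumentError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return self.classes_[np.argmax(self._joint_log_likelihood(X), axis=1)]


class RandomSubspaceEnsemble(ClassifierMixin, BaseEstimator):
    """Random subspace committee of linear discriminants, majority vote.

    Each of ``n_learners`` base discriminants is trained on a random subset of
    ``subspace_dim`` features (drawn without replacement); prediction is by
    majority vote, with ties broken toward the tied class with the largest
    summed discriminant probability. A requested subspace dimension larger
    than the available feature count is capped at fit time and logged.
    """

    def __init__(
        self,
        n_learners: int = 30,
        subspace_dim: int = 40,
        random_state: Optional[int] = None,
    ):
        self.n_learners = n_learners
        self.subspace_dim = subspace_dim
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise InvalidArgumentError("need at least 2 classes")
        p = X.shape[1]
        dim = min(self.subspace_dim, p)
        if dim < self.subspace_dim:
            logger.info(
                "subspace dimension capped from %d to %d available features",
                self.subspace_dim,
                dim,
            )
        self.subspace_dim_ = dim
        rng = np.random.default_rng(self.random_state)
        self.estimators_, self.subspaces_ = [], []
        base = LinearDiscriminantAnalysis()
        for _ in range(self.n_learners):
            feats = np.sort(rng.choice(p, size=dim, replace=False))
            est = clone(base)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # collinear-feature warnings
                est.fit(X[:, feats], y)
            self.estimators_.append(est)
            self.subspaces_.append(feats)
        self.n_features_in_ = p
        return self

    def predict(self, X):
        check_is_fitted(self, "estimators_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise InvalidArgumentError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        n = X.shape[0]
        k = self.classes_.size
        votes = np.zeros((n, k), dtype=int)
        proba_sum = np.zeros((n, k))
        class_pos = {c: i for i, c in enumerate(self.classes_)}
        for est, feats in zip(self.estimators_, self.subspaces_):
            pred = est.predict(X[:, feats])
            cols = np.array([class_pos[c] for c in pred])
            votes[np.arange(n), cols] += 1
            proba = est.predict_proba(X[:, feats])
            for j, c in enumerate(est.classes_):
                proba_sum[:, class_pos[c]] += proba[:, j]
        top = votes.max(axis=1, keepdims=True)
        tied = votes == top
        # break vote ties by the summed probability among tied classes only
        tiebreak = np.where(tied, proba_sum, -np.inf)
        return self.classes_[np.argmax(tiebreak, axis=1)]


def make_classifier(spec: ClassifierSpec, n_train: Optional[int] = None):
    """Build the estimator (with its scaling pipeline where needed)."""
    name, params, seed = spec.name, spec.params, spec.rng_seed
    if name == "bayes":
        return KernelDensityNaiveBayes()
    if name == "svm":
        est = SVC(
            kernel="poly",
            degree=2,
            coef0=1.0,
            gamma="scale",
            C=float(params["box_constraint"]),
            decision_function_shape="ovo",
        )
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    if name == "knn":
        k = int(params["n_neighbors"])
        if n_train is not None:
            k = min(k, max(1, n_train - 1))
        est = KNeighborsClassifier(n_neighbors=k, metric="euclidean", weights="uniform")
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    if name == "el":
        return RandomSubspaceEnsemble(
            n_learners=int(params["n_learners"]),
            subspace_dim=int(params["subspace_dim"]),
            random_state=seed,
        )
    if name == "ann":
        # early stopping on a 15% validation split needs enough samples for a
        # stratified holdout; fall back to full-batch training on tiny sets
        early = n_train is None or n_train >= 50
        est = MLPClassifier(
            hidden_layer_sizes=(int(params["n_hidden"]),),
            activation="tanh",
            solver="adam",
            learning_rate_init=0.01,
            max_iter=int(params["max_epochs"]),
            early_stopping=early,
            validation_fraction=0.15,
            n_iter_no_change=50,
            random_state=seed,
        )
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    raise InvalidArgumentError(f"unknown classifier {name!r}")


def _fit(est, X, y):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y)
    return est


def fit_predict(
    spec: ClassifierSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
) -> np.ndarray:
    """Fit the specified classifier and predict labels for the test features."""
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    y_train = np.asarray(y_train)
    if np.unique(y_train).size < 2:
        raise InvalidArgumentError("training data must contain at least 2 classes")
    if X_train.shape[1] != X_test.shape[1]:
        raise InvalidArgumentError(
            f"train has {X_train.shape[1]} features but test has {X_test.shape[1]}"
        )
    est = make_classifier(spec, n_train=X_train.shape[0])
    _fit(est, X_train, y_train)
    return est.predict(X_test)


def stratified_split(
    sset: SpectrumSet, train_fraction: float = 0.75, rng_seed: Optional[int] = None
) -> tuple[SpectrumSet, SpectrumSet]:
    """Per-class random split; ``ceil(train_fraction * n)`` rows go to train.

    With the default 3:1 ratio a class of 120 contributes 90/30. Deterministic
    per seed; every class needs at least 4 samples.
    """
    if not 0 < train_fraction < 1:
        raise InvalidArgumentError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(rng_seed)
    train_idx, test_idx = [], []
    for c in sset.classes:
        members = np.flatnonzero(sset.labels == c)
        if members.size < 4:
            raise StratificationError(
                f"class {c!r} has only {members.size} samples; need >= 4 to split"
            )
        perm = rng.permutation(members)
        n_tr = int(np.ceil(train_fraction * members.size))
        train_idx.append(perm[:n_tr])
        test_idx.append(perm[n_tr:])
    return (
        sset.subset(np.sort(np.concatenate(train_idx))),
        sset.subset(np.sort(np.concatenate(test_idx))),
    )


def cross_validate(
    spec: ClassifierSpec,
    X: np.ndarray | SpectrumSet,
    y: Optional[np.ndarray] = None,
    k: int = 5,
    rng_seed: Optional[int] = None,
) -> EvalResult:
    """Stratified k-fold CV accuracy and pooled confusion matrix.

    Every sample is predicted exactly once by a model not trained on it; the
    confusion matrix pools the out-of-fold predictions (rows = true classes).
    Returns an :class:`EvalResult` whose train/test accuracies are NaN-free
    placeholders (set to the CV accuracy) when only CV is requested.
    """
    if isinstance(X, SpectrumSet):
        y = X.labels
        X = X.reflectance
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise StratificationError(
            f"class {classes[np.argmin(counts)]!r} has {counts.min()} samples, "
            f"fewer than k={k}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rng_seed)
    predictions = np.empty(y.shape, dtype=y.dtype)
    for tr, te in skf.split(X, y):
        est = make_classifier(spec, n_train=tr.size)
        _fit(est, X[tr], y[tr])
        predictions[te] = est.predict(X[te])
    conf = confusion_matrix(y, predictions, labels=classes)
    cv_acc = float(np.trace(conf) / conf.sum())
    row_sums = conf.sum(axis=1)
    recall = np.divide(
        np.diag(conf), row_sums, out=np.zeros(classes.size), where=row_sums > 0
    )
    return EvalResult(
        train_accuracy=cv_acc,
        test_accuracy=cv_acc,
        cv_accuracy=cv_acc,
        confusion=conf,
        per_class_recall=recall,
        classes=classes,
    )
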