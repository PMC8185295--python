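"""The five single classifiers behind the voting ensembles.

Support vector machines with linear, polynomial and Gaussian kernels, a
classification-and-regression tree (CART), and K-nearest neighbours, each
wrapped with training-set median imputation and (for the margin/distance
learners) z-score standardization, as a scikit-learn-style estimator.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger("afrecur")

#: canonical classifier order, shared with the ensemble weight vector
CLASSIFIER_KINDS = ("svm_linear", "svm_poly", "svm_gaussian", "cart", "knn")

#: standardization applies to margin/distance learners only
_STANDARDIZED = {"svm_linear": True, "svm_poly": True, "svm_gaussian": True,
                 "cart": False, "knn": True}


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2-dimensional")
    return X


class SingleClassifier(ClassifierMixin, BaseEstimator):
    """One of the five base learners with its preprocessing baked in.

    Parameters
    ----------
    kind : one of ``svm_linear``, ``svm_poly``, ``svm_gaussian``, ``cart``,
        ``knn``.
    C, degree : SVM cost and polynomial degree (Gaussian/polynomial kernel
        scale is 1/(n_features * var) of the standardized inputs, i.e.
        roughly 1/n_features).
    n_neighbors : KNN neighbourhood size (Euclidean metric).
    min_samples_leaf : CART minimum leaf size (Gini impurity, no depth
        limit).
    seed : tie-break seed for the tree learner.

    Missing feature values are imputed with the training-column median;
    standardization parameters likewise come from training rows only.
    """

    def __init__(self, kind: str = "svm_linear", C: float = 1.0,
                 degree: int = 3, n_neighbors: int = 5,
                 min_samples_leaf: int = 1, seed: int = 0):
        self.kind = kind
        self.C = C
        self.degree = degree
        self.n_neighbors = n_neighbors
        self.min_samples_leaf = min_samples_leaf
        self.seed = seed

    def _make_learner(self):
        if self.kind == "svm_linear":
            return SVC(kernel="linear", C=self.C)
        if self.kind == "svm_poly":
            return SVC(kernel="poly", degree=self.degree, C=self.C,
                       gamma="scale")
        if self.kind == "svm_gaussian":
            return SVC(kernel="rbf", C=self.C, gamma="scale")
        if self.kind == "cart":
            return DecisionTreeClassifier(
                criterion="gini", min_samples_leaf=self.min_samples_leaf,
                random_state=self.seed)
        if self.kind == "knn":
            return KNeighborsClassifier(n_neighbors=self.n_neighbors,
                                        metric="euclidean")
        raise ValueError(f"unknown classifier kind {self.kind!r}; "
                         f"expected one of {CLASSIFIER_KINDS}")

    def _preprocess(self, X: np.ndarray) -> np.ndarray:
        X = np.where(np.isnan(X), self.impute_medians_, X)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite feature values remain after imputation")
        if _STANDARDIZED[self.kind]:
            X = (X - self.center_) / self.scale_
        return X

    def fit(self, X, y) -> "SingleClassifier":
        X = _as_matrix(X)
        y = np.asarray(y, dtype=int)
        if X.shape[0] != y.size:
            raise ValueError("X and y length mismatch")
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("training data contains a single class")
        if np.any(counts < 2):
            raise ValueError("need at least 2 training rows per class")

        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(X, axis=0)
        if not np.all(np.isfinite(med)):
            raise ValueError("a feature column is entirely missing in training")
        self.impute_medians_ = med
        Ximp = np.where(np.isnan(X), med, X)
        self.center_ = Ximp.mean(axis=0)
        scale = Ximp.std(axis=0, ddof=0)
        self.scale_ = np.where(scale > 0, scale, 1.0)
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        self.learner_ = self._make_learner()
        self.learner_.fit(self._preprocess(X), y)
        return self

    def predict(self, X) -> np.ndarray:
        X = _as_matrix(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature arity differs from training")
        return self.learner_.predict(self._preprocess(X)).astype(int)

    def decision_score(self, X) -> np.ndarray:
        """Continuous confidence for class 1, monotone in the learner's own
        decision statistic (SVM margin; class-1 probability for CART/KNN)."""
        X = self._preprocess(_as_matrix(X))
        if isinstance(self.learner_, SVC):
            return np.asarray(self.learner_.decision_function(X), dtype=float)
        proba = self.learner_.predict_proba(X)
        cls1 = int(np.where(self.learner_.classes_ == 1)[0][0])
        return np.asarray(proba[:, cls1], dtype=float)


def make_single_classifier(kind: str, config=None, seed: int = 0) -> SingleClassifier:
    """Build a :class:`SingleClassifier` from an :class:`AnalysisConfig`."""
    if config is None:
        return SingleClassifier(kind=kind, seed=seed)
    return SingleClassifier(
        kind=kind, C=config.svm_c, degree=config.svm_poly_degree,
        n_neighbors=config.knn_k, min_samples_leaf=config.cart_min_samples_leaf,
        seed=seed,
    )


def fit_single(kind: str, X, y, config=None, seed: int = 0) -> SingleClassifier:
    """Fit one base learner (thin functional wrapper)."""
    return make_single_classifier(kind, config, seed).fit(X, y)


def predict_single(model: SingleClassifier, X) -> tuple[np.ndarray, np.ndarray]:
    """Binary votes and continuous scores for ``X``."""
    return model.predict(X), model.decision_score(X)
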