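"""Weighted-voting ensembles over the five single classifiers.

An observation's five binary votes ``V(x)`` are combined with a weight
vector ``W`` on the unit simplex; the ensemble classifies

    C(x) = 1  if  W . V(x) > 0.5,   else 0,

with the boundary score 0.5 mapping to class 0. Three weightings are used:

* **MV** (mean voting): equal weights 0.2, i.e. 3-of-5 majority;
* **AWV** (accuracy-weighted voting): weights proportional to each single
  classifier's validation accuracy;
* **OWV** (optimum-weighted voting): exhaustive search over the step-0.1
  simplex grid (1001 vectors for five classifiers) for the weights that
  maximize validation accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .single import CLASSIFIER_KINDS, make_single_classifier

logger = logging.getLogger("afrecur")

N_CLASSIFIERS = len(CLASSIFIER_KINDS)


def _check_weights(weights) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1:
        raise ValueError("weights must be a vector")
    if np.any(w < -1e-9) or np.any(w > 1 + 1e-9):
        raise ValueError("weights must lie in [0, 1]")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    return w


def _check_votes(votes, k: int) -> np.ndarray:
    v = np.asarray(votes)
    if v.ndim == 1:
        v = v[None, :]
    if v.shape[1] != k:
        raise ValueError(f"vote matrix must have {k} columns, got {v.shape[1]}")
    if not np.isin(v, (0, 1)).all():
        raise ValueError("votes must be binary")
    return v.astype(float)


def ensemble_classify(weights, votes) -> tuple[np.ndarray, np.ndarray]:
    """Apply the weighted-voting rule.

    Returns ``(labels, scores)`` where ``scores = V @ W`` and
    ``labels = scores > 0.5`` (a score of exactly 0.5 yields class 0).
    """
    w = _check_weights(weights)
    v = _check_votes(votes, w.size)
    scores = v @ w
    labels = (scores > 0.5).astype(int)
    return labels, scores


def mean_voting_weights(k: int = N_CLASSIFIERS) -> np.ndarray:
    """Equal weights (0.2 each for the five classifiers)."""
    return np.full(k, 1.0 / k)


def awv_weights(validation_accuracies) -> np.ndarray:
    """Weights proportional to validation accuracy: ``w_i = acc_i / sum``."""
    acc = np.asarray(validation_accuracies, dtype=float)
    if np.any(acc < 0) or np.any(acc > 1):
        raise ValueError("accuracies must lie in [0, 1]")
    total = acc.sum()
    if total <= 0:
        raise ValueError("cannot normalize all-zero accuracies")
    return acc / total


def enumerate_weight_grid(step: float = 0.1, k: int = N_CLASSIFIERS) -> np.ndarray:
    """All non-negative weight vectors on the ``step`` grid summing to 1.

    Built from integer compositions of ``1/step`` into ``k`` parts (no
    floating-point accumulation), in lexicographic order of the vectors, so
    tie-breaks downstream are deterministic. For step 0.1 and k = 5 this is
    the C(14, 4) = 1001-point simplex grid.
    """
    denom = round(1.0 / step)
    if denom < 1 or abs(denom * step - 1.0) > 1e-9:
        raise ValueError("step must evenly divide 1")

    def compositions(total: int, parts: int):
        if parts == 1:
            yield (total,)
            return
        for first in range(total + 1):
            for rest in compositions(total - first, parts - 1):
                yield (first,) + rest

    grid = np.array(list(compositions(denom, k)), dtype=float) / denom
    return grid


def grid_search_weights(votes, labels,
                        step: float = 0.1) -> tuple[np.ndarray, float]:
    """Exhaustive simplex-grid search for the accuracy-maximizing weights.

    Ties resolve to the first vector in lexicographic enumeration order.
    Returns ``(weights, accuracy)``.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("empty validation set")
    v = _check_votes(votes, N_CLASSIFIERS)
    grid = enumerate_weight_grid(step, N_CLASSIFIERS)
    scores = v @ grid.T                       # (n_obs, n_grid)
    preds = scores > 0.5
    accs = (preds == labels[:, None].astype(bool)).mean(axis=0)
    best = int(np.argmax(accs))               # first max = lexicographic tie-break
    return grid[best], float(accs[best])


def owv_weights(validation_votes, validation_labels,
                step: float = 0.1) -> np.ndarray:
    """Optimum-weighted-voting weights (see :func:`grid_search_weights`)."""
    weights, acc = grid_search_weights(validation_votes, validation_labels, step)
    logger.info("OWV grid search: best validation accuracy %.3f at %s",
                acc, np.round(weights, 3))
    return weights


class VotingEnsembleClassifier:
    """Stand-alone scikit-learn-style voting ensemble.

    ``fit`` splits its input into an internal stratified train/validation
    partition, trains the five base learners on the training part and
    derives the voting weights from their validation votes; ``predict``
    combines the five votes with those weights. The evaluation pipeline uses
    the functional pieces directly with its own explicit splits; this class
    packages the same logic for standalone use.
    """

    def __init__(self, method: str = "owv", validation_fraction: float = 1.0 / 3.0,
                 step: float = 0.1, seed: int = 0, config=None):
        self.method = method
        self.validation_fraction = validation_fraction
        self.step = step
        self.seed = seed
        self.config = config

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("method", "validation_fraction", "step", "seed", "config")}

    def set_params(self, **params) -> "VotingEnsembleClassifier":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y) -> "VotingEnsembleClassifier":
        from .selection import make_validation_splits

        if self.method not in ("mv", "awv", "owv"):
            raise ValueError("method must be one of 'mv', 'awv', 'owv'")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        (train_idx, val_idx), = make_validation_splits(
            y, 1, self.validation_fraction, self.seed)
        self.models_ = [
            make_single_classifier(kind, self.config, self.seed)
            .fit(X[train_idx], y[train_idx])
            for kind in CLASSIFIER_KINDS
        ]
        votes = np.column_stack([m.predict(X[val_idx]) for m in self.models_])
        if self.method == "mv":
            self.weights_ = mean_voting_weights()
        elif self.method == "awv":
            accs = (votes == y[val_idx][:, None]).mean(axis=0)
            self.weights_ = awv_weights(accs)
        else:
            self.weights_ = owv_weights(votes, y[val_idx], self.step)
        self.classes_ = np.unique(y)
        return self

    def _votes(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.column_stack([m.predict(X) for m in self.models_])

    def predict(self, X) -> np.ndarray:
        labels, _ = ensemble_classify(self.weights_, self._votes(X))
        return labels

    def decision_score(self, X) -> np.ndarray:
        _, scores = ensemble_classify(self.weights_, self._votes(X))
        return scores
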