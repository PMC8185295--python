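"""Sequential forward floating selection (SFFS).

Wrapper feature selection in the floating variant: after every forward
inclusion of the best candidate feature, conditional backward exclusions are
applied as long as removing a feature strictly improves the best accuracy
recorded at the smaller subset size. The floating (backward) step is what
lets the search escape nested-subset traps — e.g. recover a pair of features
that is only jointly informative, which plain greedy forward selection can
miss.

The objective is an arbitrary deterministic callable (here: mean validation
accuracy of a classifier over bootstrap train/validation splits), so the
same search serves the single classifiers and the voting ensembles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .single import SingleClassifier, make_single_classifier

logger = logging.getLogger("afrecur")

Objective = Callable[[tuple[int, ...]], float]


@dataclass(frozen=True)
class SelectionTrace:
    """Best subset found at each size, plus the overall choice.

    ``chosen_subset`` maximizes the recorded accuracy; ties go to the
    smaller size, then to the lexicographically smallest subset.
    """

    sizes: tuple[int, ...]
    subsets: tuple[tuple[int, ...], ...]
    accuracies: tuple[float, ...]
    chosen_size: int
    chosen_subset: tuple[int, ...]
    chosen_accuracy: float
    feature_names: tuple[str, ...] | None = None

    def subset_names(self, subset: tuple[int, ...] | None = None) -> tuple[str, ...]:
        subset = self.chosen_subset if subset is None else subset
        if self.feature_names is None:
            return tuple(str(i) for i in subset)
        return tuple(self.feature_names[i] for i in subset)


class _CachedObjective:
    def __init__(self, objective: Objective):
        self._objective = objective
        self._cache: dict[tuple[int, ...], float] = {}
        self.n_evaluations = 0

    def __call__(self, subset: Sequence[int]) -> float:
        key = tuple(sorted(subset))
        if key not in self._cache:
            self._cache[key] = float(self._objective(key))
            self.n_evaluations += 1
        return self._cache[key]


def sfs(objective: Objective, n_features: int, max_size: int,
        feature_names: Sequence[str] | None = None) -> SelectionTrace:
    """Plain sequential forward selection (no floating step); baseline."""
    obj = _CachedObjective(objective)
    current: tuple[int, ...] = ()
    best: dict[int, tuple[float, tuple[int, ...]]] = {}
    for _ in range(min(max_size, n_features)):
        scores = [(obj(current + (f,)), f) for f in range(n_features)
                  if f not in current]
        acc, feat = max(scores, key=lambda t: (t[0], -t[1]))
        current = tuple(sorted(current + (feat,)))
        best[len(current)] = (acc, current)
    return _finish_trace(best, feature_names)


def sffs(objective: Objective, n_features: int, max_size: int,
         feature_names: Sequence[str] | None = None) -> SelectionTrace:
    """Floating forward selection over feature indices ``0..n_features-1``.

    Returns the per-size best subsets encountered and the overall argmax.
    The per-size record table is seeded with the plain greedy-forward path
    (the shared evaluation cache makes the overlapping prefix free), so the
    reported best accuracy at every size dominates plain sequential forward
    selection by construction. Deterministic: argmax ties within a step
    resolve to the lowest feature index.
    """
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    max_size = min(max_size, n_features)
    obj = _CachedObjective(objective)
    best: dict[int, tuple[float, tuple[int, ...]]] = {}
    current: tuple[int, ...] = ()

    def record(subset: tuple[int, ...], acc: float) -> None:
        k = len(subset)
        if k not in best or acc > best[k][0] + 1e-12:
            best[k] = (acc, tuple(sorted(subset)))

    # greedy-forward baseline path seeds the per-size records
    for _ in range(max_size):
        scores = [(obj(current + (f,)), f) for f in range(n_features)
                  if f not in current]
        acc, feat = max(scores, key=lambda t: (t[0], -t[1]))
        current = tuple(sorted(current + (feat,)))
        record(current, acc)
    current = ()

    guard = 0
    while len(current) < max_size:
        guard += 1
        if guard > 50 * max_size:  # pragma: no cover - safety net
            logger.warning("SFFS iteration guard reached; stopping search")
            break
        # forward: include the best remaining feature
        scores = [(obj(current + (f,)), f) for f in range(n_features)
                  if f not in current]
        acc, feat = max(scores, key=lambda t: (t[0], -t[1]))
        current = tuple(sorted(current + (feat,)))
        record(current, acc)
        # conditional backward: drop features while that strictly improves
        # the best accuracy recorded at the smaller size
        while len(current) > 2:
            drops = [(obj(tuple(x for x in current if x != f)), f)
                     for f in current]
            dacc, dfeat = max(drops, key=lambda t: (t[0], -t[1]))
            smaller = len(current) - 1
            if smaller in best and dacc <= best[smaller][0] + 1e-12:
                break
            current = tuple(x for x in current if x != dfeat)
            record(current, dacc)
    logger.info("SFFS finished after %d objective evaluations", obj.n_evaluations)
    return _finish_trace(best, feature_names)


def _finish_trace(best: dict[int, tuple[float, tuple[int, ...]]],
                  feature_names: Sequence[str] | None) -> SelectionTrace:
    sizes = tuple(sorted(best))
    subsets = tuple(best[k][1] for k in sizes)
    accs = tuple(best[k][0] for k in sizes)
    chosen_size = max(sizes, key=lambda k: (best[k][0], -k, tuple(-i for i in best[k][1])))
    return SelectionTrace(
        sizes=sizes, subsets=subsets, accuracies=accs,
        chosen_size=chosen_size, chosen_subset=best[chosen_size][1],
        chosen_accuracy=best[chosen_size][0],
        feature_names=None if feature_names is None else tuple(feature_names),
    )


def make_validation_splits(y: np.ndarray, n_splits: int,
                           validation_fraction: float,
                           seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Class-stratified train/validation index splits.

    Per class, ``round(n_class * validation_fraction)`` rows go to
    validation (at least one per class on each side).
    """
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_splits):
        train_idx: list[int] = []
        val_idx: list[int] = []
        for cls in np.unique(y):
            members = np.flatnonzero(y == cls)
            if members.size < 2:
                raise ValueError("each class needs at least 2 rows to split")
            n_val = int(round(members.size * validation_fraction))
            n_val = min(max(n_val, 1), members.size - 1)
            perm = rng.permutation(members)
            val_idx.extend(perm[:n_val])
            train_idx.extend(perm[n_val:])
        splits.append((np.sort(np.array(train_idx)), np.sort(np.array(val_idx))))
    return splits


def single_classifier_objective(kind: str, X: np.ndarray, y: np.ndarray,
                                splits: Sequence[tuple[np.ndarray, np.ndarray]],
                                config=None, seed: int = 0) -> Objective:
    """Mean validation accuracy of one base learner over fixed splits."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)

    def objective(subset: tuple[int, ...]) -> float:
        cols = list(subset)
        accs = []
        for train_idx, val_idx in splits:
            model = make_single_classifier(kind, config, seed)
            model.fit(X[np.ix_(train_idx, cols)], y[train_idx])
            pred = model.predict(X[np.ix_(val_idx, cols)])
            accs.append(float(np.mean(pred == y[val_idx])))
        return float(np.mean(accs))

    return objective


def sffs_select(kind: str, X, y, config=None, max_size: int | None = None,
                n_splits: int | None = None, seed: int = 0,
                feature_names: Sequence[str] | None = None) -> SelectionTrace:
    """Run SFFS for one base learner on train+validation data."""
    from .data import AnalysisConfig

    config = config or AnalysisConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    max_size = max_size or config.sffs_max_size
    n_splits = n_splits or config.n_selection_repetitions
    splits = make_validation_splits(y, n_splits, config.validation_fraction, seed)
    objective = single_classifier_objective(kind, X, y, splits, config, seed)
    return sffs(objective, X.shape[1], max_size, feature_names=feature_names)


class SFFSSelector:
    """scikit-learn-style selector: fit on (X, y), then transform to the
    chosen feature subset of one base learner."""

    def __init__(self, kind: str = "svm_linear", max_size: int = 20,
                 n_splits: int = 10, validation_fraction: float = 1.0 / 3.0,
                 seed: int = 0, config=None):
        self.kind = kind
        self.max_size = max_size
        self.n_splits = n_splits
        self.validation_fraction = validation_fraction
        self.seed = seed
        self.config = config

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in
                ("kind", "max_size", "n_splits", "validation_fraction",
                 "seed", "config")}

    def set_params(self, **params) -> "SFFSSelector":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y) -> "SFFSSelector":
        import pandas as pd

        names = tuple(X.columns) if isinstance(X, pd.DataFrame) else None
        X = np.asarray(X, dtype=float)
        self.trace_ = sffs_select(
            self.kind, X, y, config=self.config, max_size=self.max_size,
            n_splits=self.n_splits, seed=self.seed, feature_names=names)
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[list(self.trace_.chosen_subset)] = True
        return self

    def get_support(self) -> np.ndarray:
        return self.support_

    def transform(self, X):
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            return X.iloc[:, list(self.trace_.chosen_subset)]
        return np.asarray(X, dtype=float)[:, list(self.trace_.chosen_subset)]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)
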