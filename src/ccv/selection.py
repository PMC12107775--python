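"""Recursive feature elimination under cross-validation.

Features are ranked per fold by recursively refitting an impurity-importance
classifier (random forest) and halving the surviving set until the target
size is reached.  The per-fold winners are then aggregated two ways: ``rfe1``
keeps every feature selected in at least one fold (union) and ``rfe2`` only
those selected in every fold (intersection).  The target size N can be picked
automatically with the elbow rule on the mean validation importance-vs-rank
curve.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE
from sklearn.model_selection import KFold, StratifiedKFold

from .errors import ParameterError
from .types import MethodMatrix

logger = logging.getLogger(__name__)


@dataclass
class SelectionResult:
    """Per-fold selected feature sets plus their union/intersection."""

    n_target: int
    fold_sets: list[frozenset] = field(default_factory=list)
    rfe1: frozenset = frozenset()  # union over folds
    rfe2: frozenset = frozenset()  # intersection over folds

    def __post_init__(self) -> None:
        if not self.rfe2 <= self.rfe1:
            raise ParameterError("rfe2 must be a subset of rfe1")


def elbow_n(importance_curve) -> int:
    """Elbow of a decreasing importance-vs-rank curve.

    Returns the 1-based rank maximizing the perpendicular distance to the
    chord joining the first and last curve points; ties break toward the
    smaller rank, so a linear (or constant) curve yields N = 1.
    """
    y = np.asarray(importance_curve, dtype=float)
    if y.size < 3:
        raise ParameterError("importance curve needs at least 3 points")
    if np.ptp(y) == 0.0:
        warnings.warn("constant importance curve; elbow defaults to N = 1",
                      stacklevel=2)
        return 1
    x = np.arange(1.0, y.size + 1.0)
    # |cross product| with the chord; the common 1/|chord| factor is dropped
    # since it does not affect the argmax.
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    dist = np.abs(dx * (y - y[0]) - dy * (x - x[0]))
    best = dist.max()
    return int(np.flatnonzero(dist >= best - 1e-12 * max(best, 1.0))[0]) + 1


def _folds(labels, k: int, seed: int):
    """Stratified folds by biome; degrade to plain K-fold when a class is
    rarer than k (with a warning) instead of failing outright."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() >= k:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        warnings.warn(
            f"smallest class has {counts.min()} < k={k} samples; "
            "falling back to unstratified folds", stacklevel=3,
        )
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    X_dummy = np.zeros((labels.size, 1))
    return list(splitter.split(X_dummy, labels))


def _importance_estimator(seed: int, n_estimators: int = 100):
    return RandomForestClassifier(n_estimators=n_estimators, criterion="gini",
                                  random_state=seed, n_jobs=1)


def rfe_per_fold(matrix: MethodMatrix, labels, n_target: int, k: int = 10,
                 seed: int = 0, n_estimators: int = 100) -> list[frozenset]:
    """Run RFE on each training split; return the k selected feature sets.

    The elimination grid halves the surviving feature set each round
    (``step=0.5``) until exactly ``n_target`` features remain.  Deterministic
    given ``seed``.
    """
    if n_target < 1:
        raise ParameterError(f"n_target must be >= 1, got {n_target}")
    if n_target > matrix.n_features:
        raise ParameterError(
            f"n_target={n_target} exceeds the {matrix.n_features} available features"
        )
    X = matrix.values.to_numpy()
    y = np.asarray(labels)
    names = np.asarray(matrix.feature_names)
    fold_sets = []
    for i, (train, _val) in enumerate(_folds(y, k, seed)):
        if n_target == matrix.n_features:
            fold_sets.append(frozenset(names))
            continue
        selector = RFE(_importance_estimator(seed + i, n_estimators),
                       n_features_to_select=n_target, step=0.5)
        selector.fit(X[train], y[train])
        fold_sets.append(frozenset(names[selector.support_]))
    return fold_sets


def aggregate_folds(fold_sets) -> tuple[frozenset, frozenset]:
    """(rfe1, rfe2) = (union, intersection) of the per-fold feature sets."""
    fold_sets = [frozenset(s) for s in fold_sets]
    if not fold_sets:
        raise ParameterError("need at least one fold set")
    rfe1 = frozenset().union(*fold_sets)
    rfe2 = frozenset.intersection(*fold_sets)
    return rfe1, rfe2


def importance_curve(matrix: MethodMatrix, labels, k: int = 10, seed: int = 0,
                     n_estimators: int = 100) -> np.ndarray:
    """Mean sorted-importance curve across validation folds.

    For each fold an importance classifier is fitted on the training split;
    its feature importances are sorted in decreasing order and the curves are
    averaged across folds.  This is the input to :func:`elbow_n`.
    """
    X = matrix.values.to_numpy()
    y = np.asarray(labels)
    curves = []
    for i, (train, _val) in enumerate(_folds(y, k, seed)):
        est = _importance_estimator(seed + i, n_estimators)
        est.fit(X[train], y[train])
        curves.append(np.sort(est.feature_importances_)[::-1])
    return np.mean(curves, axis=0)


def select_features(matrix: MethodMatrix, labels, n_target: int | None = None,
                    k: int = 10, seed: int = 0,
                    n_estimators: int = 100) -> SelectionResult:
    """Full selection pass: (optional) elbow-chosen N, per-fold RFE, aggregation."""
    if n_target is None:
        curve = importance_curve(matrix, labels, k=k, seed=seed,
                                 n_estimators=n_estimators)
        n_target = elbow_n(curve)
        logger.info("elbow selected n_target=%d for %s", n_target, matrix.method)
    fold_sets = rfe_per_fold(matrix, labels, n_target, k=k, seed=seed,
                             n_estimators=n_estimators)
    rfe1, rfe2 = aggregate_folds(fold_sets)
    return SelectionResult(n_target=n_target, fold_sets=fold_sets,
                           rfe1=rfe1, rfe2=rfe2)
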