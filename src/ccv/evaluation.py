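"""Quantifying biome separation per representation.

No clustering algorithm is run anywhere in this module: the biome labels ARE
the cluster assignments, and the three validity indices (Calinski-Harabasz,
Dunn, silhouette) score how well each representation separates them in
Euclidean space.  Classification performance is measured with stratified
k-fold cross-validation for three real classifiers and two trivial baselines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.model_selection import StratifiedKFold

from .errors import FoldError, ParameterError, ZeroVarianceError
from .selection import SelectionResult
from .types import MethodMatrix

CLASSIFIERS = ("rf", "knn", "nb", "random_equal", "most_frequent")
FEATURE_SETS = ("full", "rfe1", "rfe2")


def euclidean_distances(matrix) -> np.ndarray:
    """Symmetric Euclidean distance matrix between sample rows."""
    X = matrix.values.to_numpy() if isinstance(matrix, MethodMatrix) else np.asarray(matrix, float)
    return squareform(pdist(X, metric="euclidean"))


def _as_groups(labels):
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    return labels, uniq


def calinski_harabasz(matrix, labels) -> float:
    """Between/within dispersion ratio with label-defined groups.

    ``(B/(k-1)) / (W/(n-k))`` where B and W are the between- and within-group
    sums of squared Euclidean deviations from the respective centroids.
    """
    X = matrix.values.to_numpy() if isinstance(matrix, MethodMatrix) else np.asarray(matrix, float)
    if X.ndim == 1:
        X = X[:, None]
    labels, uniq = _as_groups(labels)
    n, k = X.shape[0], uniq.size
    if k < 2:
        raise ParameterError("Calinski-Harabasz needs at least 2 clusters")
    if n <= k:
        raise ParameterError("Calinski-Harabasz needs more samples than clusters")
    centroid = X.mean(axis=0)
    between = 0.0
    within = 0.0
    for g in uniq:
        grp = X[labels == g]
        c = grp.mean(axis=0)
        between += grp.shape[0] * float(((c - centroid) ** 2).sum())
        within += float(((grp - c) ** 2).sum())
    if within == 0.0:
        raise ZeroVarianceError("zero within-cluster variance; CH is undefined")
    return (between / (k - 1)) / (within / (n - k))


def dunn_index(distances, labels, eps: float = 1e-12) -> float:
    """Classic Dunn index: min inter-cluster pair distance over max diameter.

    A zero maximum diameter (all clusters collapsed to points) is guarded
    with ``eps`` so perfectly tight clusters yield a large finite value.
    """
    D = np.asarray(distances, float)
    labels, uniq = _as_groups(labels)
    if uniq.size < 2:
        raise ParameterError("Dunn index needs at least 2 clusters")
    min_between = np.inf
    max_diameter = 0.0
    for i, a in enumerate(uniq):
        ia = np.flatnonzero(labels == a)
        block = D[np.ix_(ia, ia)]
        if ia.size > 1:
            max_diameter = max(max_diameter, float(block.max()))
        for b in uniq[i + 1:]:
            ib = np.flatnonzero(labels == b)
            min_between = min(min_between, float(D[np.ix_(ia, ib)].min()))
    return min_between / max(max_diameter, eps)


def mean_silhouette(distances, labels) -> float:
    """Mean silhouette width from a precomputed distance matrix.

    For each sample, ``a`` is the mean distance to its own cluster (excluding
    itself) and ``b`` the smallest mean distance to another cluster; the
    width is ``(b - a)/max(a, b)``.  Singleton clusters contribute 0
    (standard convention).
    """
    D = np.asarray(distances, float)
    labels, uniq = _as_groups(labels)
    if uniq.size < 2:
        raise ParameterError("silhouette needs at least 2 clusters")
    n = D.shape[0]
    widths = np.zeros(n)
    for i in range(n):
        own = np.flatnonzero(labels == labels[i])
        if own.size == 1:
            widths[i] = 0.0
            continue
        a = D[i, own[own != i]].mean()
        b = min(D[i, labels == g].mean() for g in uniq if g != labels[i])
        widths[i] = (b - a) / max(a, b)
    return float(widths.mean())


def normalize_across_variants(values) -> np.ndarray:
    """Min-max normalize one metric across compared variants.

    A constant metric maps to all zeros with a warning.  NaN entries (e.g.
    variants whose index was undefined) are passed through.
    """
    vals = np.asarray(values, float)
    if np.sum(~np.isnan(vals)) < 2:
        raise ParameterError("need at least 2 variants to normalize")
    lo, hi = np.nanmin(vals), np.nanmax(vals)
    if hi == lo:
        warnings.warn("constant metric across variants; normalizing to 0",
                      stacklevel=2)
        out = np.zeros_like(vals)
        out[np.isnan(vals)] = np.nan
        return out
    return (vals - lo) / (hi - lo)


def pca_project(matrix, n_components: int = 2):
    """Centered PCA projection.

    Returns (coordinates DataFrame, explained-variance fractions).
    """
    X = matrix.values.to_numpy() if isinstance(matrix, MethodMatrix) else np.asarray(matrix, float)
    if X.shape[0] < 2:
        raise ParameterError("PCA needs at least 2 samples")
    n_components = min(n_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    index = matrix.values.index if isinstance(matrix, MethodMatrix) else None
    df = pd.DataFrame(coords, index=index,
                      columns=[f"PC{i + 1}" for i in range(n_components)])
    return df, pca.explained_variance_ratio_


def umap_project(matrix, n_components: int = 2, seed: int = 0, **kwargs):
    """2-D UMAP embedding via the established implementation (optional).

    The embedding is treated as non-deterministic across library versions and
    is excluded from acceptance checks.
    """
    import umap  # deferred: optional heavy dependency

    X = matrix.values.to_numpy() if isinstance(matrix, MethodMatrix) else np.asarray(matrix, float)
    reducer = umap.UMAP(n_components=n_components, random_state=seed, **kwargs)
    return reducer.fit_transform(X)


def make_classifier(name: str, seed: int = 0, n_classes: int | None = None):
    """Instantiate one of the five evaluated classifiers."""
    if name == "rf":
        return RandomForestClassifier(n_estimators=100, criterion="gini",
                                      random_state=seed, n_jobs=1)
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=5, weights="uniform",
                                    metric="euclidean")
    if name == "nb":
        # "without prior probabilities" -> uniform class priors
        priors = None if n_classes is None else np.full(n_classes, 1.0 / n_classes)
        return GaussianNB(priors=priors)
    if name == "random_equal":
        return DummyClassifier(strategy="uniform", random_state=seed)
    if name == "most_frequent":
        return DummyClassifier(strategy="most_frequent")
    raise ParameterError(f"unknown classifier {name!r}; allowed: {CLASSIFIERS}")


def crossval_classify(matrix, labels, classifier: str, k: int = 10,
                      seed: int = 0) -> float:
    """Mean validation accuracy under stratified k-fold CV."""
    return float(np.mean(crossval_scores(matrix, labels, classifier, k=k, seed=seed)))


def crossval_scores(matrix, labels, classifier: str, k: int = 10,
                    seed: int = 0) -> np.ndarray:
    X = matrix.values.to_numpy() if isinstance(matrix, MethodMatrix) else np.asarray(matrix, float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise FoldError(
            f"smallest class has {counts.min()} samples; cannot build {k} stratified folds"
        )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = []
    for fold, (train, val) in enumerate(splitter.split(X, y)):
        clf = make_classifier(classifier, seed=seed + fold, n_classes=classes.size)
        clf.fit(X[train], y[train])
        scores.append(float((clf.predict(X[val]) == y[val]).mean()))
    return np.asarray(scores)


@dataclass
class EvaluationReport:
    """18-variant grid of clustering indices and classifier accuracies."""

    table: pd.DataFrame  # MultiIndex (method, feature_set) x metric columns

    @property
    def n_variants(self) -> int:
        return len(self.table)


def evaluate_variants(matrices: dict, selections: dict | None = None,
                      labels_by_sample=None, k: int = 10, seed: int = 0,
                      classifiers=CLASSIFIERS) -> EvaluationReport:
    """Score every (representation, feature-set) variant.

    Parameters
    ----------
    matrices:
        Mapping method tag -> MethodMatrix.
    selections:
        Mapping method tag -> SelectionResult (or None for full-set-only).
    labels_by_sample:
        Mapping or Series sample -> biome label.
    """
    selections = selections or {}
    rows = []
    index = []
    for tag, matrix in matrices.items():
        sel: SelectionResult | None = selections.get(tag)
        for fset in FEATURE_SETS:
            if fset == "full":
                sub = matrix
            elif sel is None:
                continue
            else:
                chosen = sel.rfe1 if fset == "rfe1" else sel.rfe2
                sub = matrix.subset(chosen)
            index.append((tag, fset))
            rows.append(_score_variant(sub, labels_by_sample, k, seed, classifiers))
    table = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(
        index, names=("method", "feature_set")))
    for metric in ("ch", "dunn", "silhouette"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table[f"{metric}_norm"] = normalize_across_variants(table[metric])
    return EvaluationReport(table=table)


def _score_variant(matrix: MethodMatrix, labels_by_sample, k, seed, classifiers):
    row: dict = {"n_features": matrix.n_features}
    labels = np.asarray([labels_by_sample[s] for s in matrix.samples])
    if matrix.n_features == 0:
        warnings.warn(f"variant of {matrix.method} has no features; scoring NaN",
                      stacklevel=2)
        for m in ("ch", "dunn", "silhouette"):
            row[m] = np.nan
        for c in classifiers:
            row[f"acc_{c}"] = np.nan
        return row
    D = euclidean_distances(matrix)
    try:
        row["ch"] = calinski_harabasz(matrix, labels)
    except ZeroVarianceError:
        row["ch"] = np.nan
    row["dunn"] = dunn_index(D, labels)
    row["silhouette"] = mean_silhouette(D, labels)
    for c in classifiers:
        row[f"acc_{c}"] = crossval_classify(matrix, labels, c, k=k, seed=seed)
    return row
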