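import numpy as np
import pandas as pd
import pytest

from ccv import evaluation as ev
from ccv.errors import FoldError, ParameterError, ZeroVarianceError
from ccv.types import MethodMatrix

# ---------------------------------------------------------------------------
# independent loop-based oracles
# ---------------------------------------------------------------------------

def loop_euclidean(X):
    n = len(X)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            D[i, j] = sum((a - b) ** 2 for a, b in zip(X[i], X[j])) ** 0.5
    return D


def loop_ch(X, labels):
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    uniq = sorted(set(labels))
    n, k = len(X), len(uniq)
    grand = X.mean(axis=0)
    B = W = 0.0
    for g in uniq:
        pts = X[[i for i, l in enumerate(labels) if l == g]]
        c = pts.mean(axis=0)
        B += len(pts) * sum((c - grand) ** 2)
        for p in pts:
            W += sum((p - c) ** 2)
    return (B / (k - 1)) / (W / (n - k))


def loop_dunn(D, labels):
    uniq = sorted(set(labels))
    between = min(
        D[i, j]
        for i in range(len(labels)) for j in range(len(labels))
        if labels[i] != labels[j]
    )
    diameter = max(
        D[i, j]
        for i in range(len(labels)) for j in range(len(labels))
        if labels[i] == labels[j]
    )
    return between / max(diameter, 1e-12)


def loop_silhouette(D, labels):
    n = len(labels)
    widths = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            widths.append(0.0)
            continue
        a = sum(D[i, j] for j in same) / len(same)
        b = min(
            sum(D[i, j] for j in range(n) if labels[j] == g)
            / sum(1 for j in range(n) if labels[j] == g)
            for g in set(labels) if g != labels[i]
        )
        widths.append((b - a) / max(a, b))
    return sum(widths) / n


TOY_X = np.array([[0.0], [2.0], [10.0], [12.0]])
TOY_LABELS = np.array(["a", "a", "b", "b"])


def _random_instance(seed, n=10, p=3, k=3):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    labels = rng.choice([f"g{i}" for i in range(k)], size=n)
    while len(set(labels)) < 2:
        labels = rng.choice([f"g{i}" for i in range(k)], size=n)
    return X, labels


class TestEuclidean:
    def test_3_4_5(self):
        D = ev.euclidean_distances(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert D[0, 1] == pytest.approx(5.0)

    def test_identical_rows(self):
        D = ev.euclidean_distances(np.array([[1.0, 2.0], [1.0, 2.0]]))
        assert D[0, 1] == 0.0

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 4))
        np.testing.assert_allclose(ev.euclidean_distances(X), loop_euclidean(X),
                                   atol=1e-12)


class TestCalinskiHarabasz:
    def test_hand_value_50(self):
        # W = 4, B = 100 -> (100/1)/(4/2) = 50
        assert ev.calinski_harabasz(TOY_X, TOY_LABELS) == pytest.approx(50.0)

    def test_zero_within_variance_raises(self):
        X = np.array([[0.0], [0.0], [5.0], [5.0]])
        with pytest.raises(ZeroVarianceError):
            ev.calinski_harabasz(X, TOY_LABELS)

    def test_single_cluster_raises(self):
        with pytest.raises(ParameterError):
            ev.calinski_harabasz(TOY_X, ["a"] * 4)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_loop_oracle(self, seed):
        X, labels = _random_instance(seed)
        assert ev.calinski_harabasz(X, labels) == pytest.approx(
            loop_ch(X, labels), abs=1e-12)


class TestDunn:
    def test_hand_value_4(self):
        D = ev.euclidean_distances(TOY_X)
        assert ev.dunn_index(D, TOY_LABELS) == pytest.approx(4.0)  # 8/2

    def test_monotone_in_separation(self):
        values = []
        for shift in (10.0, 20.0, 40.0):
            X = np.array([[0.0], [2.0], [shift], [shift + 2.0]])
            values.append(ev.dunn_index(ev.euclidean_distances(X), TOY_LABELS))
        assert values[0] < values[1] < values[2]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_loop_oracle(self, seed):
        X, labels = _random_instance(seed)
        D = ev.euclidean_distances(X)
        assert ev.dunn_index(D, labels) == pytest.approx(loop_dunn(D, labels),
                                                         abs=1e-12)

    def test_zero_diameter_guarded(self):
        X = np.array([[0.0], [0.0], [5.0], [5.0]])
        D = ev.euclidean_distances(X)
        assert np.isfinite(ev.dunn_index(D, TOY_LABELS))


class TestSilhouette:
    def test_hand_value(self):
        # mean of {9/11, 7/9, 7/9, 9/11}
        D = ev.euclidean_distances(TOY_X)
        expected = (9 / 11 + 7 / 9 + 7 / 9 + 9 / 11) / 4
        assert ev.mean_silhouette(D, TOY_LABELS) == pytest.approx(expected,
                                                                  abs=1e-12)
        assert expected == pytest.approx(0.7980, abs=5e-5)

    def test_approaches_one_with_separation(self):
        X = np.array([[0.0], [1e-9], [1e9], [1e9 + 1e-9]])
        D = ev.euclidean_distances(X)
        assert ev.mean_silhouette(D, TOY_LABELS) > 0.999999

    def test_singleton_cluster_contributes_zero(self):
        X = np.array([[0.0], [10.0], [12.0]])
        D = ev.euclidean_distances(X)
        val = ev.mean_silhouette(D, ["a", "b", "b"])
        assert val == pytest.approx(loop_silhouette(D, ["a", "b", "b"]), abs=1e-12)

    def test_single_cluster_raises(self):
        with pytest.raises(ParameterError):
            ev.mean_silhouette(np.zeros((3, 3)), ["a"] * 3)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_loop_oracle(self, seed):
        X, labels = _random_instance(seed)
        D = ev.euclidean_distances(X)
        assert ev.mean_silhouette(D, labels) == pytest.approx(
            loop_silhouette(D, labels), abs=1e-12)


class TestIndexMonotonicity:
    def test_translation_increases_indices(self):
        base = np.array([[0.0, 0], [1, 1], [0, 1], [5, 5], [6, 6], [5, 6]])
        labels = ["a"] * 3 + ["b"] * 3
        ch, dunn, sil = [], [], []
        for shift in (0.0, 5.0, 20.0):
            X = base.copy()
            X[3:] += shift
            D = ev.euclidean_distances(X)
            ch.append(ev.calinski_harabasz(X, labels))
            dunn.append(ev.dunn_index(D, labels))
            sil.append(ev.mean_silhouette(D, labels))
        assert ch[0] < ch[1] < ch[2]
        assert dunn[0] < dunn[1] < dunn[2]
        assert sil[0] <= sil[1] <= sil[2]


class TestNormalize:
    def test_minmax(self):
        np.testing.assert_allclose(ev.normalize_across_variants([2, 4, 6]),
                                   [0, 0.5, 1])

    def test_constant_warns_and_zeros(self):
        with pytest.warns(UserWarning):
            np.testing.assert_allclose(ev.normalize_across_variants([5.0, 5.0]),
                                       [0.0, 0.0])

    def test_rank_invariance(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=10)
        out = ev.normalize_across_variants(vals)
        assert (np.argsort(out) == np.argsort(vals)).all()


class TestPCA:
    def test_collinear_explains_everything(self):
        X = np.outer(np.arange(5.0), [1.0, 2.0])
        _, evr = ev.pca_project(X)
        assert evr[0] == pytest.approx(1.0)

    def test_isotropic_gaussian_splits_evenly(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4000, 2))
        _, evr = ev.pca_project(X)
        assert evr[0] == pytest.approx(0.5, abs=0.05)

    def test_rank2_distances_preserved(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 2)) @ rng.normal(size=(2, 6))
        coords, _ = ev.pca_project(X, n_components=2)
        np.testing.assert_allclose(ev.euclidean_distances(coords.to_numpy()),
                                   ev.euclidean_distances(X), atol=1e-8)


class TestCrossval:
    def _mat(self, X, tag="planted"):
        return MethodMatrix(tag, pd.DataFrame(
            np.asarray(X, float), index=[f"s{i}" for i in range(len(X))]))

    def test_separable_knn_perfect(self):
        X = np.concatenate([np.zeros(10), np.ones(10) * 10])[:, None]
        y = ["a"] * 10 + ["b"] * 10
        assert ev.crossval_classify(self._mat(X), y, "knn", k=5) == 1.0

    def test_most_frequent_rate(self):
        y = ["A"] * 7 + ["B"] * 3
        X = np.zeros((10, 1))
        clf = ev.make_classifier("most_frequent")
        clf.fit(X, y)
        assert (clf.predict(X) == y).mean() == pytest.approx(0.7)

    def test_random_equal_near_uniform(self):
        rng = np.random.default_rng(0)
        y = rng.choice([f"b{i}" for i in range(11)], size=100_000)
        clf = ev.make_classifier("random_equal", seed=1)
        X = np.zeros((y.size, 1))
        clf.fit(X, y)
        acc = (clf.predict(X) == y).mean()
        assert acc == pytest.approx(1 / 11, abs=0.005)

    def test_random_equal_ignores_features(self):
        rng = np.random.default_rng(3)
        y = list("ab" * 10)
        accs = []
        for scale in (1.0, 100.0):
            X = rng.normal(scale=scale, size=(20, 3))
            accs.append(ev.crossval_scores(self._mat(X), y, "random_equal",
                                           k=5, seed=9))
        # same seed, same labels -> identical fold-wise accuracies
        np.testing.assert_array_equal(accs[0], accs[1])

    def test_fold_error_when_class_too_small(self):
        y = ["a"] * 9 + ["b"]
        with pytest.raises(FoldError):
            ev.crossval_classify(self._mat(np.zeros((10, 1))), y, "rf", k=5)

    def test_unknown_classifier(self):
        with pytest.raises(ParameterError):
            ev.make_classifier("svm")


class TestEvaluateVariants:
    def test_grid_and_baseline_gap(self, tiny_study):
        from ccv.core import build_method_matrix, filter_uniform
        from ccv.selection import select_features

        table, preds, meta, _ = tiny_study
        matrices, selections = {}, {}
        for tag in ("mfp_avg", "cc_avg"):
            m = filter_uniform(build_method_matrix(tag, table, preds))
            matrices[tag] = m
            selections[tag] = select_features(
                m, meta.labels_for(m.samples), n_target=3, k=3, seed=0,
                n_estimators=30)
        report = ev.evaluate_variants(matrices, selections, meta.table["biome"],
                                      k=3, seed=0)
        assert report.n_variants == 6  # 2 methods x 3 feature sets
        full = report.table.loc[("mfp_avg", "full")]
        for clf in ("rf", "knn", "nb"):
            assert (full[f"acc_{clf}"]
                    >= full["acc_random_equal"] + 0.3)
            assert (full[f"acc_{clf}"]
                    >= full["acc_most_frequent"] + 0.3)
        for col in ("ch_norm", "dunn_norm", "silhouette_norm"):
            vals = report.table[col].dropna()
            assert (vals >= 0).all() and (vals <= 1).all()
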