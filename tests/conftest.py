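import numpy as np
import pandas as pd
import pytest

from ccv.simulate import make_fixture
from ccv.types import MethodMatrix


@pytest.fixture(scope="session")
def tiny_study():
    """Small complete study: 3 biomes x 5 samples, 20 fp + 10 cc characteristics."""
    return make_fixture("tiny")


@pytest.fixture(scope="session")
def tiny_table(tiny_study):
    return tiny_study[0]


@pytest.fixture(scope="session")
def tiny_preds(tiny_study):
    return tiny_study[1]


@pytest.fixture(scope="session")
def tiny_meta(tiny_study):
    return tiny_study[2]


def planted_matrix(seed, n_classes=3, n_per=20, n_feat=200, n_inf=5, effect=6.0):
    """Gaussian noise matrix with ``n_inf`` fully class-informative columns.

    Each informative column shifts the class means by ``effect`` standard
    deviations in a rotating -1/0/+1 pattern, so every informative feature
    separates at least two classes strongly.  Returns (matrix, labels,
    informative feature-name set).
    """
    rng = np.random.default_rng(seed)
    y = np.repeat([f"c{i}" for i in range(n_classes)], n_per)
    X = rng.normal(size=(y.size, n_feat))
    for j in range(n_inf):
        for i in range(n_classes):
            X[y == f"c{i}", j] += effect * (((i + j) % n_classes) - 1)
    cols = [f"f{j}" for j in range(n_feat)]
    matrix = MethodMatrix("planted", pd.DataFrame(
        X, columns=cols, index=[f"s{i}" for i in range(y.size)]))
    return matrix, y, frozenset(cols[:n_inf])
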