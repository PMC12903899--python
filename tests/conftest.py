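import numpy as np
import pandas as pd
import pytest

import guidescreen as gs


@pytest.fixture(scope="session")
def small_study():
    """A modest depletion screen reused across read-only tests."""
    return gs.simulate_study(seed=11, n_guides=800, genome_length=60_000, coverage=115)


@pytest.fixture()
def toy_enrichment_table():
    """3-guide, 2-sample enrichment table with a closed-form score."""
    counts = pd.DataFrame(
        {"c1": [100, 100, 100], "e1": [800, 100, 100]}, index=["g1", "g2", "g3"]
    )
    return gs.CountTable(
        counts=counts,
        conditions={"c1": "control", "e1": "experimental"},
        direction="enrichment",
    )


@pytest.fixture(scope="session")
def tiny_genome():
    return gs.generate_genome(8000, gc=0.5, seed=3, contig_id="tiny")


class LabelLookup:
    """Perfect predictor: echoes the known label for every input it was given."""

    def __init__(self, X_all, y_all):
        self._map = {x.tobytes(): yi for x, yi in zip(X_all, y_all)}

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.array([self._map[x.tobytes()] for x in X])


class FixedFunctionRegressor:
    """Deterministic data-independent predictor: a fixed linear read-out of the input."""

    def fit(self, X, y):
        rng = np.random.default_rng(99)
        self._w = rng.normal(size=X.shape[1] * X.shape[2])
        return self

    def predict(self, X):
        return X.reshape(X.shape[0], -1) @ self._w


class ConstantRegressor:
    def fit(self, X, y):
        self._c = float(np.mean(y))
        return self

    def predict(self, X):
        return np.full(X.shape[0], self._c)


@pytest.fixture()
def fixed_function_factory():
    return lambda seed=None: FixedFunctionRegressor()


@pytest.fixture()
def label_lookup_cls():
    return LabelLookup


@pytest.fixture()
def constant_factory():
    return lambda seed=None: ConstantRegressor()
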