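import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ctdselect import FeatureMatrix, ProteinSequence, load_grouping_table

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def core7():
    return load_grouping_table("core7")


@pytest.fixture(scope="session")
def extended13():
    return load_grouping_table("extended13")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_matrix(X, y, names=None, ids=None) -> FeatureMatrix:
    """Build a FeatureMatrix from plain arrays (test helper)."""
    X = np.asarray(X, dtype=float)
    names = names or [f"f{j + 1}" for j in range(X.shape[1])]
    ids = ids or [f"s{i + 1}" for i in range(X.shape[0])]
    return FeatureMatrix(
        pd.DataFrame(X, index=ids, columns=names),
        pd.Series(np.asarray(y, dtype=int), index=ids),
    )


@pytest.fixture
def separable_matrix(rng):
    """60 samples x 5 features; f1 nearly equals the label, the rest is noise."""
    n = 60
    y = np.array([1] * 30 + [0] * 30)
    X = rng.normal(size=(n, 5))
    X[:, 0] = y + rng.normal(scale=0.01, size=n)
    return make_matrix(X, y)


@pytest.fixture
def tiny_sequences():
    pos = [
        ProteinSequence("p1", "MFILCWVMFILCWVAG"),
        ProteinSequence("p2", "WWVVLLIIFFMMCCGA"),
    ]
    neg = [
        ProteinSequence("n1", "NQDEKRNQDEKRSTGA"),
        ProteinSequence("n2", "KKRRDDEEQQNNSTGA"),
        ProteinSequence("n3", "DEKRNQDEKRNQAGST"),
    ]
    return pos, neg
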