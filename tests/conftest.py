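import numpy as np
import pytest

from growl import Partition, TrialDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(n=40, d=3, M=4, seed=0, R=None):
    """Small generic dataset with uniform propensities."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(-1, 1, size=(n, d))
    A = rng.integers(1, M + 1, size=n)
    if R is None:
        R = rng.normal(size=n)
    prop = np.full((n, M), 1.0 / M)
    return TrialDataset(X=X, A=A, R=np.asarray(R, dtype=float), prop=prop)


@pytest.fixture
def small_dataset():
    return make_dataset()


def two_group_toy(n=300, d=2, M=4, effect=3.0, seed=0, noise=0.0):
    """Homogeneous two-group toy: arms {1,2} share effect -e*x1, arms {3,4}
    share +e*x1; strong signal, optional outcome noise."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(-1, 1, size=(n, d))
    A = rng.integers(1, M + 1, size=n)
    sign = np.where(A <= M // 2, -1.0, 1.0)
    R = 1.0 + X[:, 0] + effect * X[:, 0] * sign + noise * rng.standard_normal(n)
    prop = np.full((n, M), 1.0 / M)
    ds = TrialDataset(X=X, A=A, R=R, prop=prop)
    truth = Partition([1] * (M // 2) + [2] * (M - M // 2), 2)
    return ds, truth
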