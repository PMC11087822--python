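import numpy as np
import pytest

from adrpred import SyntheticSpec, planted_benchmark
from adrpred.matrixdata import FeatureTable, InteractionMatrix


@pytest.fixture(scope="session")
def small_bench():
    """Desk-scale masked benchmark shared by harness tests."""
    return planted_benchmark(SyntheticSpec(M=60, N=50, p=80, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_interaction(rng, m=8, n=6, density=0.3, prefix=""):
    values = (rng.uniform(size=(m, n)) < density).astype(int)
    return InteractionMatrix(
        values,
        [f"{prefix}a{i}" for i in range(m)],
        [f"{prefix}d{j}" for j in range(n)],
    )


def random_features(rng, n=6, p=10, name="feat", prefix=""):
    values = rng.integers(0, 2, size=(n, p))
    return FeatureTable(
        values,
        [f"{prefix}d{j}" for j in range(n)],
        [f"f{k}" for k in range(p)],
        name,
    )
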