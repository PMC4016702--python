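import numpy as np
import pytest

from reffree_ewas import DesignMatrix, MethylationMatrix


def make_Y(values: np.ndarray) -> MethylationMatrix:
    m, n = values.shape
    return MethylationMatrix(
        values=values,
        cpg_ids=[f"cg{j:05d}" for j in range(m)],
        sample_ids=[f"s{i}" for i in range(n)],
        check_range=False,
    )


def make_X(x: np.ndarray) -> DesignMatrix:
    return DesignMatrix(
        values=np.column_stack([np.ones(x.size), x]),
        column_names=["intercept", "x"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture
def small_dataset(rng):
    """10 CpGs x 12 samples, exact linear structure plus mild noise."""
    n, m = 12, 10
    x = rng.uniform(0, 1, size=n)
    X = make_X(x)
    B = rng.uniform(-0.05, 0.05, size=(m, 2))
    B[:, 0] = rng.uniform(0.2, 0.8, size=m)
    E = rng.normal(0, 0.01, size=(m, n))
    Y = make_Y(B @ X.values.T + E)
    return Y, X, B, E
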