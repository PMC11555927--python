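import numpy as np
import pytest

from atckit.changes import PairedChangeSeries
from atckit.synthetic_data import GeneratorSpec, gen_bivariate_normal


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_pairs():
    """Hand-checkable pairs: 2 concordant, 1 discordant, one zero product."""
    return PairedChangeSeries.from_arrays(
        x_delta=[1.0, -1.0, 2.0, 0.0],
        y_delta=[2.0, -3.0, -1.0, 1.0],
    )


@pytest.fixture(scope="session")
def bivnormal_10k():
    return gen_bivariate_normal(GeneratorSpec("bivariate_normal", 10_000, seed=11))


def random_pairs(rng, n, zeros=False):
    """Random paired changes for brute-force comparisons."""
    x = rng.normal(0, 2, n)
    y = rng.normal(0, 2, n)
    if zeros:
        idx = rng.integers(0, n, max(1, n // 10))
        x[idx[: idx.size // 2]] = 0.0
        y[idx[idx.size // 2 :]] = 0.0
    return PairedChangeSeries.from_arrays(x, y)
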