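import numpy as np
import pytest

from mrcl import DataMatrix, build_pair_index


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_data(rng):
    """4-variable, 60-sample matrix with one strongly coupled pair."""
    n = 60
    a = rng.normal(size=n)
    b = a + 0.3 * rng.normal(size=n)
    c = rng.normal(size=n)
    d = rng.normal(size=n)
    return DataMatrix(np.column_stack([a, b, c, d]), ["A", "B", "C", "D"])


@pytest.fixture
def pairs3():
    return build_pair_index(3)
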