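import numpy as np
import pytest

from imputerank import NumericTable, gen_two_linear_xy


@pytest.fixture
def small_table():
    """5x3 complete table with simple values."""
    vals = np.array(
        [
            [1.0, 10.0, 100.0],
            [2.0, 20.0, 200.0],
            [3.0, 30.0, 300.0],
            [4.0, 40.0, 400.0],
            [5.0, 50.0, 500.0],
        ]
    )
    return NumericTable(vals, col_ids=["a", "b", "c"])


@pytest.fixture
def xy_table():
    return gen_two_linear_xy(200, 0.05, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
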