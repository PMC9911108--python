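import numpy as np
import pandas as pd
import pytest

from hingeselect.preprocessing import CohortTable


@pytest.fixture
def rng():
    return np.random.default_rng(20230126)


@pytest.fixture
def toy_table():
    """12 subjects, 3 variables, 2 holes, balanced-ish labels."""
    rng = np.random.default_rng(7)
    data = pd.DataFrame(
        rng.standard_normal((12, 3)),
        columns=["a", "b", "c"],
        index=[f"S{i}" for i in range(12)],
    )
    data.loc["S0", "a"] = np.nan
    data.loc["S5", "c"] = np.nan
    labels = pd.Series([1, 1, 1, 1, 1, -1, -1, -1, -1, -1, -1, -1],
                       index=data.index, dtype=np.int8)
    return CohortTable(data=data, labels=labels)


@pytest.fixture
def separable_design():
    """Linearly separable 1-D toy: class by the sign of x, wide margin."""
    rng = np.random.default_rng(3)
    n = 20
    x = np.r_[rng.normal(-2.0, 0.3, n // 2), rng.normal(2.0, 0.3, n // 2)]
    X = np.column_stack([np.ones(n), x])
    y = np.r_[-np.ones(n // 2), np.ones(n // 2)]
    return X, y
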