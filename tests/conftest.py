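import numpy as np
import pandas as pd
import pytest

from tegrn.exprio import ExpressionMatrix, clock_labels


@pytest.fixture
def rng():
    return np.random.default_rng(20221107)


@pytest.fixture
def small_matrix():
    """10 genes x 60 timepoints at 3-min cadence, mixed rhythms, seeded."""
    r = np.random.default_rng(42)
    n_t = 60
    hours = 7.0 + np.arange(n_t) * 3 / 60.0
    rows = {}
    for i in range(10):
        base = 20 + 10 * np.cos(2 * np.pi * (hours - i) / 24)
        rows[f"g{i}"] = np.maximum(base * np.exp(r.normal(0, 0.2, n_t)), 0.0)
    df = pd.DataFrame(rows).T
    df.columns = clock_labels("07:00", n_t, 3.0)
    df.index.name = "gene"
    return ExpressionMatrix(df, 3.0)


@pytest.fixture
def tiny_matrix():
    df = pd.DataFrame(
        [[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]],
        index=pd.Index(["a", "b"], name="gene"),
        columns=["07:00", "07:03", "07:06"],
    )
    return ExpressionMatrix(df, 3.0)
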