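import numpy as np
import pandas as pd
import pytest

from conexnet.core_io import ConditionMap, ExpressionMatrix, PhenotypeTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_expr():
    """4 features x 6 samples, log scale, with two correlated pairs."""
    rng = np.random.default_rng(7)
    base = rng.standard_normal(6)
    data = np.vstack(
        [
            base + 0.01 * rng.standard_normal(6),
            base + 0.01 * rng.standard_normal(6),
            rng.standard_normal(6),
            rng.standard_normal(6),
        ]
    )
    df = pd.DataFrame(
        data, index=["f1", "f2", "f3", "f4"], columns=[f"s{i}" for i in range(6)]
    )
    return ExpressionMatrix(df, scale="log_normalized")


@pytest.fixture
def counts_two_conditions():
    """Counts matrix over two conditions of three samples each."""
    rng = np.random.default_rng(11)
    data = rng.poisson(50, size=(5, 6)).astype(float)
    df = pd.DataFrame(
        data,
        index=[f"m{i}" for i in range(5)],
        columns=[f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)],
    )
    cmap = ConditionMap({f"a{i}": "A" for i in range(3)} | {f"b{i}": "B" for i in range(3)})
    return ExpressionMatrix(df, scale="counts"), cmap


@pytest.fixture
def phenotypes_small():
    rng = np.random.default_rng(3)
    df = pd.DataFrame(
        rng.standard_normal((6, 3)),
        index=[f"s{i}" for i in range(6)],
        columns=["traitA", "traitB", "traitC"],
    )
    df.iloc[0, 1] = np.nan
    return PhenotypeTable(df)
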