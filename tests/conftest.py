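import numpy as np
import pandas as pd
import pytest

from micronetstab.tabio import AsvTable


@pytest.fixture
def small_table() -> AsvTable:
    """10 taxa x 12 samples, reproducible random counts with no zero-variance rows."""
    rng = np.random.default_rng(42)
    counts = rng.poisson(20, size=(10, 12)) + rng.integers(0, 5, size=(10, 12))
    df = pd.DataFrame(
        counts,
        index=[f"t{i}" for i in range(10)],
        columns=[f"s{j}" for j in range(12)],
    )
    return AsvTable(df)


@pytest.fixture
def tiny_table() -> AsvTable:
    df = pd.DataFrame(
        [[5, 1, 0], [2, 2, 2], [0, 3, 7]],
        index=["a", "b", "c"],
        columns=["s1", "s2", "s3"],
    )
    return AsvTable(df)
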