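import numpy as np
import pandas as pd
import pytest

from methylflux import CountMatrix


@pytest.fixture
def toy_counts() -> pd.DataFrame:
    return pd.DataFrame(
        {"s1": [10, 0, 5, 100], "s2": [20, 1, 7, 200]},
        index=["geneA", "geneB", "geneC", "ERCC-00002"],
    )


@pytest.fixture
def toy_count_matrix(toy_counts) -> CountMatrix:
    meta = pd.DataFrame(
        {"condition": ["NC", "STM"], "timepoint_h": [0.0, 4.0], "replicate": [1, 1]},
        index=pd.Index(["s1", "s2"], name="sample"),
    )
    return CountMatrix(counts=toy_counts, metadata=meta)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
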