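import numpy as np
import pandas as pd
import pytest

from mgomics import FeatureTable


@pytest.fixture
def small_counts() -> FeatureTable:
    """3 samples x 4 taxa count table with one zero-heavy sample."""
    data = pd.DataFrame(
        [[1.0, 2.0, 3.0, 0.0],
         [4.0, 4.0, 4.0, 4.0],
         [0.0, 0.0, 5.0, 0.0]],
        index=["S1", "S2", "S3"],
        columns=["A", "B", "C", "D"],
    )
    return FeatureTable(data, feature_kind="taxon_cluster")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
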