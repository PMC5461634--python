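import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_matrix():
    """3 lncRNAs x 4 samples (2 normal + 2 cancer)."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0, 8.0], [2.5, 2.0, 1.5, 1.0]],
        index=["lncA", "lncB", "lncC"],
        columns=["n1", "n2", "c1", "c2"],
    )
    group = pd.Series(["normal", "normal", "cancer", "cancer"], index=values.columns)
    return values, group


@pytest.fixture
def rng():
    return np.random.default_rng(42)
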