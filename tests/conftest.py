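import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_dataset(rng, m=6, n1=8, n2=8, labels=("A", "B")):
    """Small random continuous expression matrix with two classes."""
    values = rng.normal(size=(m, n1 + n2))
    matrix = pd.DataFrame(
        values,
        index=[f"f{i}" for i in range(m)],
        columns=[f"s{j}" for j in range(n1 + n2)],
    )
    y = pd.Series([labels[0]] * n1 + [labels[1]] * n2, index=matrix.columns)
    return matrix, y


@pytest.fixture
def rng():
    return np.random.default_rng(20260917)
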