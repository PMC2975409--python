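import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from plasmapanel import IntensityMatrix

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_matrix(values: np.ndarray, n_case: int, scale: str = "log2",
                prefix: str = "p") -> IntensityMatrix:
    """Wrap an array as an IntensityMatrix: first n_case columns are cases."""
    n_feat, n_samp = values.shape
    rows = [f"{prefix}{i}" for i in range(n_feat)]
    cols = [f"s{i}" for i in range(n_samp)]
    groups = {c: ("case" if i < n_case else "control")
              for i, c in enumerate(cols)}
    return IntensityMatrix(pd.DataFrame(values, index=rows, columns=cols),
                           groups, scale=scale)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_matrix(rng):
    """8 proteins x (4 case + 4 control) continuous log2 matrix."""
    return make_matrix(rng.normal(20.0, 1.0, size=(8, 8)), n_case=4)
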