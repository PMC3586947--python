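import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_expr(rng):
    """6 genes x 40 samples with two correlated blocks of 3 genes."""
    m = 40
    e1 = rng.standard_normal(m)
    e2 = rng.standard_normal(m)
    rows = []
    for e in (e1, e2):
        for _ in range(3):
            rows.append(e + 0.4 * rng.standard_normal(m))
    return pd.DataFrame(
        np.vstack(rows),
        index=[f"g{i}" for i in range(1, 7)],
        columns=[f"s{j}" for j in range(1, m + 1)],
    )


@pytest.fixture
def random_mi_matrix(rng):
    """Symmetric non-negative matrix standing in for a pairwise MI matrix."""

    def make(n=5, scale=1.0, seed=None):
        gen = np.random.default_rng(seed) if seed is not None else rng
        a = gen.uniform(0, scale, size=(n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        return a

    return make
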