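import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import zygoscan as z

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def f1_table() -> z.TwoLocusTable:
    """Hand-checked reference table: n=100, D_AABB=0.14, Delta=0.16875."""
    return z.TwoLocusTable(np.array([[30, 10, 0], [10, 30, 5], [0, 5, 10]]))


@pytest.fixture
def epistatic_table() -> z.TwoLocusTable:
    """Double-heterozygote excess with Delta=0: corners 10, center 60 (n=100)."""
    return z.TwoLocusTable(np.array([[10, 0, 10], [0, 60, 0], [10, 0, 10]]))


@pytest.fixture
def independence_table() -> z.TwoLocusTable:
    """Counts proportional to products of marginals: all LDs exactly zero."""
    row = np.array([20, 50, 30])
    col = np.array([40, 40, 20])
    return z.TwoLocusTable(np.outer(row, col))  # n = 100*100


def random_tables(rng: np.random.Generator, k: int, n: int = 500) -> np.ndarray:
    """k multinomial count tables from random points on the 9-simplex."""
    probs = rng.dirichlet(np.ones(9), size=k)
    return np.vstack([rng.multinomial(n, p) for p in probs]).reshape(k, 3, 3)
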