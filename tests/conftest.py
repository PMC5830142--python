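import numpy as np
import pytest

from hhrineq import default_study_config, generate_cities
from hhrineq.ranks import fractional_rank


@pytest.fixture(scope="session")
def study_table():
    """One realization of the default 322-city study scenario."""
    return generate_cities(default_study_config(seed=11))


@pytest.fixture(scope="session")
def small_table():
    """A small synthetic table for cheap pipeline tests."""
    import dataclasses

    cfg = dataclasses.replace(default_study_config(seed=5), n_cities=120)
    return generate_cities(cfg)


@pytest.fixture
def toy_ranked():
    """Midpoint ranks for four units with living standards 10 < 20 < 30 < 40."""
    return fractional_rank(np.array([10.0, 20.0, 30.0, 40.0]), method="midpoint")


def brute_force_ci(h, r):
    """Independent oracle: C = 2 cov_pop(h, r) / mean(h) written out longhand."""
    h = np.asarray(h, dtype=float)
    r = np.asarray(r, dtype=float)
    n = len(h)
    mu = sum(h) / n
    rbar = sum(r) / n
    cov = sum((h[i] - mu) * (r[i] - rbar) for i in range(n)) / n
    return 2.0 * cov / mu
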