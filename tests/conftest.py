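import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

logging.getLogger("topodriver").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort():
    """Compact cohort with 3 planted drivers, used across the suite."""
    from topodriver import CohortConfig, simulate_cohort

    cfg = CohortConfig(seed=11, n_samples=120, n_genes=400, n_drivers=3,
                       n_passengers=60, passenger_rate=5.0, n_hypermutators=0)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_representation(small_cohort):
    from topodriver import (MapperConfig, build_representation,
                            correlation_distance, filter_embedding,
                            select_variable_genes)

    E, M, truth = small_cohort
    var = select_variable_genes(E, 400)
    D = correlation_distance(E, var)
    mc = MapperConfig(resolution=10, gain=3.0)
    coords = filter_embedding(D, mc, expression=E, genes=var)
    return build_representation(E, mc, genes=var, distance=D, coords=coords)


@pytest.fixture(scope="session")
def two_cluster_cohort():
    """Two expression clusters with one driver at 10% prevalence."""
    from topodriver import CohortConfig, simulate_cohort

    cfg = CohortConfig(seed=7, n_samples=200, n_genes=400, n_subtypes=2,
                       n_drivers=1, driver_prevalence=(0.10, 0.10),
                       n_passengers=50, passenger_rate=4.0, n_hypermutators=0)
    return simulate_cohort(cfg)


def random_graph_and_feature(rng, n_max=20):
    """Random symmetric zero-diagonal adjacency and nonnegative feature."""
    n = int(rng.integers(2, n_max + 1))
    A = (rng.random((n, n)) < 0.4).astype(float)
    A = np.triu(A, k=1)
    A = A + A.T
    e = rng.random(n)
    e[rng.random(n) < 0.3] = 0.0
    if e.sum() == 0:
        e[int(rng.integers(0, n))] = 1.0
    return A, e
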