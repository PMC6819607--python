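import numpy as np
import pandas as pd
import pytest

from rdsim.netpop import NetworkedPopulation, build_population
from rdsim.sampler import SamplerConfig, rds_sample


def make_population(edges, groups=None, degrees=None, pi=0.5, hx=1.0, **kw):
    """Assemble a NetworkedPopulation from an explicit edge list."""
    edges = np.asarray(edges, dtype=np.int64)
    n = int(edges.max()) + 1 if len(edges) else int(kw.pop("n"))
    d = np.zeros(n, dtype=np.int64)
    np.add.at(d, edges[:, 0], 1)
    np.add.at(d, edges[:, 1], 1)
    if degrees is None:
        degrees = d
    groups = np.zeros(n, dtype=np.int64) if groups is None else np.asarray(groups)
    rng = np.random.default_rng(kw.pop("seed", 0))
    same = groups[edges[:, 0]] == groups[edges[:, 1]]
    return NetworkedPopulation(
        degrees=np.asarray(degrees, dtype=np.int64),
        groups=groups,
        x_predict=rng.normal(size=n) + 2.0 * groups,
        x_null=rng.normal(size=n),
        edges=edges,
        pi=pi,
        hx=hx,
        t_ii=int(same.sum()),
        t_ij=int(len(edges) - same.sum()),
        omega=1.0,
    )


@pytest.fixture(scope="session")
def pop10():
    """One default 10,000-node population (pi=0.10, Hx=1.0)."""
    return build_population(0.10, 1.0, rng=np.random.default_rng(42))


@pytest.fixture(scope="session")
def pop30():
    """pi=0.30, Hx=1.0 population (Table 1 reference cell)."""
    return build_population(0.30, 1.0, rng=np.random.default_rng(43))


@pytest.fixture(scope="session")
def samples30(pop30):
    """Sixty default-config RDS samples from pop30, shared across tests."""
    adj = pop30.adjacency()
    rng = np.random.default_rng(7)
    return [rds_sample(pop30, SamplerConfig(), rng, adjacency=adj) for _ in range(60)]


@pytest.fixture()
def sample30(samples30):
    return samples30[0]
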