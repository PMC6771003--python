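import numpy as np
import pytest

from igcsim import PhaseSchedule, SimParams, init_population
from igcsim.fixtures import FixtureSpec, make_planted_matrix
from igcsim.matrix import PolarizedSNPMatrix


@pytest.fixture(scope="session")
def tiny_params():
    """Small, fast parameter set used by most simulator unit tests."""
    return SimParams(N=20, L=200, mu=0.01, R_c1=0.5, R_c2=0.5, R_c3=0.5,
                     R_s1=0.5, R_s2=50.0, C_total=2.0, s=0.0,
                     schedule=PhaseSchedule(200, 600, 1200, 1800),
                     seed=1234)


@pytest.fixture()
def tiny_pop(tiny_params):
    return init_population(tiny_params)


def random_matrix(rng, n_sites=30, n_alleles=8, gap_frac=0.0,
                  paralogs=("P1",) * 4 + ("P2",) * 2 + ("P3",) * 2):
    """A random polarized matrix where every site has >=1 derived call."""
    paralogs = list(paralogs)[:n_alleles]
    while len(paralogs) < n_alleles:
        paralogs.append("P1")
    data = (rng.random((n_sites, n_alleles)) < rng.uniform(
        0.1, 0.9, size=(n_sites, 1))).astype(np.int8)
    data[data.sum(axis=1) == 0, 0] = 1
    if gap_frac:
        gaps = rng.random(data.shape) < gap_frac
        data[gaps] = -1
        data[(data == 1).sum(axis=1) == 0, 0] = 1
    return PolarizedSNPMatrix(
        positions=np.arange(1, n_sites + 1),
        anc=np.full(n_sites, "A"), data=data,
        allele_ids=[f"a{i}" for i in range(n_alleles)],
        paralogs=paralogs, total_sites=n_sites)


@pytest.fixture()
def rng():
    return np.random.default_rng(20261001)


@pytest.fixture(scope="session")
def planted_small():
    spec = FixtureSpec(
        n_alleles={"P1": 6, "P2": 5, "P3": 4},
        category_counts={"shared-all": 2, "private-P2": 1,
                         "shared-P1P3": 3, "private-P1": 2},
        fixed_diffs={("P1", "P2"): 4},
        seed=7)
    return spec, make_planted_matrix(spec)
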