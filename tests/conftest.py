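import numpy as np
import pytest

from hemisnet import AnalysisConfig, make_fixture


@pytest.fixture(scope="session")
def tiny_cohort():
    """2 datasets x 6 subjects; smoke-test scale."""
    return make_fixture("tiny")


@pytest.fixture(scope="session")
def null_cohort():
    """5 datasets, 60 subjects, no injected asymmetry."""
    return make_fixture("null")


@pytest.fixture(scope="session")
def effect_cohort():
    """5 datasets, 200 cases + 200 controls, right-fusiform coupling 0.6."""
    return make_fixture("effect")


@pytest.fixture
def fast_config():
    """Desk-scale analysis settings for tests."""
    return AnalysisConfig(n_permutations=99, n_null_networks=3, rng_seed=11)


@pytest.fixture(scope="session")
def random_graphs():
    """Seeded family of small binary graphs of 2..12 nodes, mixed density."""
    rng = np.random.default_rng(123)
    graphs = []
    for n in range(2, 13):
        for density in (0.2, 0.4, 0.7, 0.95):
            for _ in range(4):
                a = (rng.random((n, n)) < density).astype(float)
                a = np.triu(a, k=1)
                a = a + a.T
                graphs.append(a)
    return graphs
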