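import numpy as np
import pytest

from falsesignal import CountMatrix, GroupSimConfig, NBSimConfig
from falsesignal.simulate import simulate_grouped, simulate_nb_two_groups


@pytest.fixture(scope="session")
def nb_default():
    """One default two-group NB replicate (500 genes x 1000 cells)."""
    return simulate_nb_two_groups(NBSimConfig(seed=1), 0)


@pytest.fixture(scope="session")
def small_nb():
    """A small NB replicate for fast imputer/stat tests."""
    cfg = NBSimConfig(n_cells=120, n_genes=60, seed=7)
    return simulate_nb_two_groups(cfg, 0)


@pytest.fixture(scope="session")
def small_grouped():
    """A small labelled grouped dataset (3 types)."""
    cfg = GroupSimConfig(
        n_cells=240, n_genes=300, n_groups=3, de_total_fraction=0.2,
        libsize_logmean=8.0, seed=11,
    )
    return simulate_grouped(cfg)


def toy_matrix(values, scale="raw", labels=None):
    values = np.asarray(values)
    return CountMatrix(
        values=values,
        genes=[f"g{i}" for i in range(values.shape[0])],
        cells=[f"c{i}" for i in range(values.shape[1])],
        labels=labels,
        scale=scale,
    )


@pytest.fixture
def make_matrix():
    return toy_matrix
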