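import numpy as np
import pytest

from dietrep import (
    CollapseMode,
    IncidenceMatrix,
    SynthParams,
    collapse_pcrs,
    collapse_pool,
    generate_dataset,
)


@pytest.fixture(scope="session")
def default_dataset():
    """Full-size default design: 20 x 15 x 3, 150 taxa."""
    return generate_dataset(SynthParams(seed=11))


@pytest.fixture(scope="session")
def default_mats(default_dataset):
    cube, _, _ = default_dataset
    return collapse_pcrs(cube, CollapseMode("single_random", seed=12))


@pytest.fixture(scope="session")
def default_pool_mat(default_dataset):
    _, pools, _ = default_dataset
    return collapse_pool(pools, CollapseMode("single_random", seed=12))


@pytest.fixture()
def small_dataset():
    return generate_dataset(SynthParams(I=5, J=6, K=2, T=25, seed=3))


def random_matrix(rng, m, t, p=0.4):
    return IncidenceMatrix("x", rng.random((m, t)) < p, [f"t{i}" for i in range(t)])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
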