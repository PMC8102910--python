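import numpy as np
import pytest

from polystall import synthdata


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_proteome():
    """A small planted proteome shared by read-only tests."""
    config = synthdata.SimConfig(
        seed=7, n_genes=30,
        planted={"a": 2, "b": 2, "c": 2, "d": 2, "icp": 2},
    )
    proteins, cdss, truth = synthdata.generate_proteome(config)
    return config, proteins, cdss, truth
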