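import numpy as np
import pytest

from zstrata import simdata


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def two_strata_cfg():
    """Two-stratum Z chromosome: a sharp 0.30 -> 0.10 divergence step."""
    return simdata.SimConfig(
        strata_spec=(
            simdata.StratumSpec("S0", 100, 0.30, 0.0),
            simdata.StratumSpec("S1", 100, 0.10, 0.5),
        ),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_tree():
    return simdata.random_ultrametric_tree(16, rng=np.random.default_rng(42))
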