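import numpy as np
import pytest

from localcov.simulate import SimulationConfig, SimulatedWorld


@pytest.fixture(scope="session")
def tiny_config():
    """Desk-miniature genome: 3 blocks, 300 SNPs, 600 samples per study."""
    return SimulationConfig(seed=4242, n1=600, n2=600, n_ref=200,
                            block_sizes=(120, 90, 90), clump_size_max=20,
                            rho_local=0.01)


@pytest.fixture(scope="session")
def tiny_world(tiny_config):
    return SimulatedWorld(tiny_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
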