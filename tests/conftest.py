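import numpy as np
import pytest

from tmefib.synth import PHENOTYPE_A, PHENOTYPE_B, generate_fiber_network


@pytest.fixture(scope="session")
def network_a():
    return generate_fiber_network(PHENOTYPE_A, shape=(256, 256), seed=3)


@pytest.fixture(scope="session")
def network_b():
    return generate_fiber_network(PHENOTYPE_B, shape=(256, 256), seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
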