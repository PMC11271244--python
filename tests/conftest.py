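import numpy as np
import pytest

from spannot.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def laminar_sim():
    """Small laminar tissue shared by detector/MRF/EM tests."""
    return simulate(SimulationConfig(shape=(30, 30), n_genes=100,
                                     markers_per_pattern=3, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
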