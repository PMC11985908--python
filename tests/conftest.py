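import numpy as np
import pytest

from multiscint import materials, reconstruction


@pytest.fixture(scope="session")
def surrogate():
    """Default three-layer multicolor surrogate stack (0.1 mm layers)."""
    return materials.surrogate_stack(0.1)


@pytest.fixture(scope="session")
def single_top():
    """Single-layer comparison stack of the same total thickness."""
    return materials.single_layer_stack("surrogate_top", 0.3)


@pytest.fixture(scope="session")
def calibration(surrogate):
    """Session-wide calibration table at a reduced desk scale."""
    return reconstruction.calibrate(surrogate, n_per_energy=500,
                                    rng=np.random.default_rng(1234))


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
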