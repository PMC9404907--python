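import numpy as np
import pytest

from retireg import PhantomSpec, vessel_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20220805)


@pytest.fixture(scope="session")
def phantom64():
    """A deterministic 64x64 vessel phantom shared across tests."""
    return vessel_phantom(PhantomSpec(size=64, n_trees=2, branch_depth=3,
                                      vessel_width=(1.0, 3.0), seed=7))
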