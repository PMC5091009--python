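import numpy as np
import pytest

from barrelkit import synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def micelle():
    """Small synthetic protein-in-micelle trajectory with labeled probes."""
    traj, probes = synth.generate_micelle_system(n_water=150, n_frames=4, seed=7)
    return traj, probes
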