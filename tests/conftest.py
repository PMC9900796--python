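import numpy as np
import pytest

from megdyn import spatialnulls, synthgen


@pytest.fixture(scope="session")
def geometry():
    return synthgen.gen_parcellation(50, seed=1)


@pytest.fixture(scope="session")
def ensemble(geometry):
    return spatialnulls.make_spin_ensemble(geometry, n_perms=500, seed=2)


@pytest.fixture(scope="session")
def latent(geometry):
    return synthgen.gen_smooth_map(geometry, 0.8, seed=3)


@pytest.fixture(scope="session")
def white_noise():
    return np.random.default_rng(12345).standard_normal(40000)
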