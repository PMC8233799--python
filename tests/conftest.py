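import numpy as np
import pytest
from hypothesis import settings

import rnlmstar as rs

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """Parameters sized for 16x16 oracle comparisons."""
    return rs.FilterParams(h=0.4, radp=2, rads=4, degc=0.2, omega=3)


@pytest.fixture
def band_phantom():
    """Layered phantom without particles, 48x48."""
    spec = rs.PhantomSpec(
        size=(48, 48), n_bands=3, n_particles=0, edge_blur_sigma=0.8, seed=7
    )
    return rs.make_phantom(spec)


@pytest.fixture
def particle_spec():
    return rs.PhantomSpec(
        size=(48, 48),
        n_bands=1,
        n_particles=3,
        particle_radius_px=1,
        particle_contrast=0.5,
        edge_blur_sigma=0.0,
        seed=3,
        band_levels=(0.3,),
    )
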