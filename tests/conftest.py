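import numpy as np
import pytest

import fnirs_sensfield as fs


@pytest.fixture(scope="session")
def small_params():
    """Compact corrugated phantom used across unit tests."""
    return fs.PhantomParams(grid_shape=(30, 30, 26), sulcal_depth_mm=8.0,
                            gyral_wavelength_mm=20.0, seed=42)


@pytest.fixture(scope="session")
def small_phantom(small_params):
    return fs.generate_head_phantom(small_params)


@pytest.fixture(scope="session")
def flat_params():
    return fs.PhantomParams(grid_shape=(30, 30, 26), sulcal_depth_mm=0.0, seed=1)


@pytest.fixture(scope="session")
def flat_phantom(flat_params):
    return fs.generate_head_phantom(flat_params)


@pytest.fixture(scope="session")
def flat_montage(flat_phantom):
    _, scalp, _ = flat_phantom
    return fs.place_optodes(scalp, 2, 2, 30.0)


@pytest.fixture(scope="session")
def small_projector(small_phantom):
    head, _, pial = small_phantom
    return fs.VoronoiProjector(head, pial)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230213)
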