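import numpy as np
import pytest

from kelpscan.pipeline import build_reference_profiles
from kelpscan.reference_model import default_subtraction_config
from kelpscan.synthcam import make_materials


@pytest.fixture(scope="session")
def materials():
    return make_materials()


@pytest.fixture(scope="session")
def config():
    return default_subtraction_config()


@pytest.fixture(scope="session")
def profiles(materials):
    """Seaweed/belt reference profiles from 10,000 clean draws each."""
    return build_reference_profiles(materials, n_pixels=10_000, seed=202)


@pytest.fixture()
def rng():
    return np.random.default_rng(4242)


def tiny_cube(data, wavelengths=None):
    """Small HyperCube helper used across test modules."""
    from kelpscan.hypercube_io import HyperCube

    data = np.asarray(data)
    if wavelengths is None:
        wavelengths = 400.0 + 10.0 * np.arange(data.shape[2])
    return HyperCube(data=data, wavelengths=wavelengths)
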