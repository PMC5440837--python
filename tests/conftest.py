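import numpy as np
import pytest

from groovedock import synthetic_data as sd


@pytest.fixture(scope="session")
def pair():
    """Long (groove-filled) / short (groove-bearing) bundle pair."""
    return sd.make_long_short_pair()


@pytest.fixture(scope="session")
def receptor():
    """Four-subunit receptor fixture with protruding M4 helices."""
    return sd.make_receptor_fixture()


@pytest.fixture(scope="session")
def planted(pair, receptor):
    """A docked scene planted at 40 degrees."""
    return sd.plant_complex(pair, receptor, true_angle=40.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
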