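import numpy as np
import pytest

from carbdock import intermediates as im
from carbdock import synthetic_data as sd
from carbdock.conformers import ConformerLibrary


@pytest.fixture(scope="session")
def species_a():
    return im.load_species("A")


@pytest.fixture(scope="session")
def species_b():
    return im.load_species("B")


@pytest.fixture(scope="session")
def toy_cation():
    return sd.make_toy_cation([2, 2, 1])


@pytest.fixture(scope="session")
def toy_receptor():
    return sd.make_toy_receptor(sd.FixtureSpec(seed=3), variant="T")


@pytest.fixture(scope="session")
def aligned_ws():
    return sd.make_aligned_workspace(sd.FixtureSpec(seed=3), variant="T")


@pytest.fixture(scope="session")
def toy_library(aligned_ws):
    return ConformerLibrary([aligned_ws.conformer], provenance="toy")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
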