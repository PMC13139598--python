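import numpy as np
import pytest

from enzscape.multibasin import build_multibasin_model
from enzscape.synthetic import make_adk_like_two_state, make_toy_two_state


@pytest.fixture(scope="session")
def adk_refs():
    """The synthetic 214-residue two-state enzyme references."""
    return make_adk_like_two_state()


@pytest.fixture(scope="session")
def adk_model(adk_refs):
    return build_multibasin_model(*adk_refs)


@pytest.fixture(scope="session")
def toy_refs():
    return make_toy_two_state(20, 14.0, seed=1)


@pytest.fixture(scope="session")
def toy_model(toy_refs):
    return build_multibasin_model(*toy_refs)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
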