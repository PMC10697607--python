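import numpy as np
import pytest

from ctenoswim import (Morphometry, BeatParams, FluidProperties, build_body,
                       place_ctenes, default_coefficients)


@pytest.fixture(scope="session")
def morph():
    return Morphometry()


@pytest.fixture(scope="session")
def fluid():
    return FluidProperties()


@pytest.fixture(scope="session")
def body(morph, fluid):
    return build_body(morph, fluid.rho)


@pytest.fixture(scope="session")
def coeffs(body):
    return default_coefficients(body)


@pytest.fixture(scope="session")
def placements(morph):
    return place_ctenes(morph)


@pytest.fixture(scope="session")
def beat():
    return BeatParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(20230891)
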