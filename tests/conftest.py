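import numpy as np
import pytest

from limbicnet.phantoms import build_atlas


@pytest.fixture(scope="session")
def atlas64():
    """Reference atlas at the default desk-scale grid."""
    return build_atlas((64, 64, 40))


@pytest.fixture(scope="session")
def atlas32():
    """Small atlas for cheap tests."""
    return build_atlas((32, 32, 20))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
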