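import numpy as np
import pytest

from pegconf import (
    GeometrySpec,
    build_ideal_helix,
    build_ideal_linear,
)


@pytest.fixture(scope="session")
def crystal() -> GeometrySpec:
    return GeometrySpec.crystal()


@pytest.fixture(scope="session")
def helix6(crystal):
    return build_ideal_helix(6, crystal)


@pytest.fixture(scope="session")
def linear6(crystal):
    return build_ideal_linear(6, crystal)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
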