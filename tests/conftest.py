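import numpy as np
import pytest

from oximap.chromophores import load_default_basis
from oximap.phantoms import ground_truth_protocol, make_reference
from oximap.sfdi import build_lut

REFERENCE_OPTICS = {
    659.0: (0.018, 1.2),
    691.0: (0.016, 1.15),
    731.0: (0.015, 1.1),
    851.0: (0.012, 1.0),
}


@pytest.fixture(scope="session")
def basis():
    return load_default_basis()


@pytest.fixture(scope="session")
def lut():
    """Default 256x256 table with the inverse interpolant prebuilt."""
    table = build_lut()
    table.ensure_inverse()
    return table


@pytest.fixture(scope="session")
def small_lut():
    table = build_lut(n_mua=96, n_musp=96)
    table.ensure_inverse()
    return table


@pytest.fixture
def reference_factory():
    def factory(shape=(32, 32), pixel_pitch=0.5, seed=0, **protocol_overrides):
        protocol = ground_truth_protocol(**protocol_overrides)
        return make_reference(
            REFERENCE_OPTICS, protocol, shape=shape, pixel_pitch=pixel_pitch
        )

    return factory
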