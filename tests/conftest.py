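import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from petcrt import (
    OpticalTransportSpec,
    PhotodetectorSpec,
    ScintillatorSpec,
)


@pytest.fixture(scope="session")
def optics():
    """Standard optical transport: a=0.7, d1=0.00873 ns, d2=0.0186 ns/cm."""
    return OpticalTransportSpec()


@pytest.fixture(scope="session")
def lso():
    """3 x 3 x 30 mm LSO reference crystal (yield set per test)."""
    return ScintillatorSpec(
        attenuation_length_cm=1.2,
        refractive_index=1.82,
        length_cm=3.0,
        rise_time_ns=0.0,
        decay_time_ns=37.0,
        photoelectron_yield=4000,
    )


@pytest.fixture(scope="session")
def photodetector():
    """High-performance photodetector: 0.2 ns jitter, 0.2/2 ns SER."""
    return PhotodetectorSpec(jitter_fwhm_ns=0.2)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
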