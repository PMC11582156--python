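import numpy as np
import pytest

from uteqmt.core_model import MTProtocol, TissueParams, simulate_spectrum
from uteqmt.phantom import MIDPOINT_PARAMS, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def protocol() -> MTProtocol:
    return MTProtocol()


@pytest.fixture(scope="session")
def midpoint() -> TissueParams:
    return MIDPOINT_PARAMS


@pytest.fixture(scope="session")
def midpoint_spectrum(midpoint, protocol) -> np.ndarray:
    return simulate_spectrum(midpoint, protocol)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A 2x2 mosaic of 6x6 chips for fast integration tests."""
    chips = tuple(
        TissueParams(mmf=m, k_ab=k, t1_obs=0.240, t2a=0.8e-3)
        for m in (0.30, 0.60)
        for k in (10.0, 60.0)
    )
    return PhantomSpec(chips=chips, chip_size=6, layout=(2, 2))


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def midpoint_chip_phantom():
    """A single 18x18 chip at the midpoint parameter set."""
    spec = PhantomSpec(chips=(MIDPOINT_PARAMS,), layout=(1, 1))
    return generate_phantom(spec)
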