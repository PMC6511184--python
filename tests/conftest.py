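import numpy as np
import pytest

from octaperf import ScanGeometry, generate_faz


@pytest.fixture(scope="session")
def small_geometry() -> ScanGeometry:
    return ScanGeometry(3.0, 120)


@pytest.fixture(scope="session")
def small_faz(small_geometry):
    return generate_faz(0.103, small_geometry, seed=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
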