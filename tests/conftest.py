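import numpy as np
import pytest

from podnirs import WavelengthGrid, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """48 samples x 3 replicates on the full grid; shared across tests."""
    return generate_dataset(n=48, replicates=3, seed=42)


@pytest.fixture(scope="session")
def pod_dataset():
    """The full 144-sample x 6-replicate study design."""
    return generate_dataset(n=144, replicates=6, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def short_grid():
    """A compact 100-point grid for unit tests that don't need 1050 points."""
    return WavelengthGrid(1000.0, 1198.0, 2.0)
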