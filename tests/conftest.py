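import numpy as np
import pytest

from iqrank import LatentQualityModel, generate_scan_pool


def truthful_oracle(values: dict):
    """Consistent oracle preferring the item with the larger value."""

    def oracle(a, b):
        return a if values[a] > values[b] else b

    return oracle


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_pool():
    """The canonical 30-patient, 510-scan pool."""
    return generate_scan_pool(30, LatentQualityModel(seed=7))
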