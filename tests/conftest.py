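import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nervequant import RoiPolygon, rasterize_roi
from nervequant.synthetic import default_roi

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def octagon_roi() -> RoiPolygon:
    """Standard 128x128-frame octagonal nerve ROI used across the suite."""
    return default_roi((128, 128))


@pytest.fixture(scope="session")
def octagon_mask(octagon_roi):
    return rasterize_roi(octagon_roi, (128, 128))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
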