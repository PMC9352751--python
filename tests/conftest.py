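import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vegidx.grids import GridGeometry

settings.register_profile(
    "vegidx",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("vegidx")


@pytest.fixture
def geom8() -> GridGeometry:
    return GridGeometry(8, 8, origin_x=0.0, origin_y=2000.0, pixel_size=250.0, crs_id="EPSG:5070")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20210607)
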