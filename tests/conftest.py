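import numpy as np
import pytest

from edgegrid.projection import LambertAzimuthalEqualArea, ProjectionSpec


@pytest.fixture
def spec() -> ProjectionSpec:
    """Projection centred on the default synthetic domain, default grids."""
    return ProjectionSpec(projection=LambertAzimuthalEqualArea(22.0, 38.5))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20210301)
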