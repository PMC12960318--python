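import numpy as np
import pytest

from maglevpiv.synthetic import (default_channel_geometry, default_image_spec,
                                 default_laser_plane, default_motion_model)


@pytest.fixture(scope="session")
def geom():
    return default_channel_geometry()


@pytest.fixture(scope="session")
def plane():
    return default_laser_plane()


@pytest.fixture(scope="session")
def motion_model():
    return default_motion_model()


@pytest.fixture(scope="session")
def image_spec():
    return default_image_spec()


@pytest.fixture
def rng():
    return np.random.default_rng(20250)
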