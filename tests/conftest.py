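import numpy as np
import pytest

from linacqa.core_io import PlanarImage


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def flat_image():
    """A featureless mid-gray raster (used for error-path tests)."""
    return PlanarImage(
        pixels=np.full((64, 64), 0.5),
        pixel_pitch_mm=0.392,
        source_detector_distance_mm=1500.0,
    )
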