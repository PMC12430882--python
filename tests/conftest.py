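import numpy as np
import pytest

from specrec import (CameraResponse, IlluminantCube, IlluminantSpectrum,
                     RadianceCube, ReflectanceCube, WavelengthGrid)


@pytest.fixture
def grid8() -> WavelengthGrid:
    return WavelengthGrid.uniform(400.0, 700.0, 8)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def random_scene(grid8, rng):
    """A small random reflectance/illuminant/camera triple on one grid."""
    reflectance = ReflectanceCube(rng.uniform(0.0, 1.0, (6, 5, 8)), grid8)
    illum = IlluminantSpectrum(rng.uniform(0.1, 1.0, 8), grid8)
    response = CameraResponse(rng.uniform(0.0, 1.0, (3, 8)), grid8)
    return reflectance, illum, response
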