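import numpy as np
import pytest

from pet_hetero.pet_metrics import BoundingBox, SuvVolume
from pet_hetero.phantom import PhantomSpec, make_phantom

# reference linear-decay tumor: SUV(r) = 10 * (1 - r / 20 mm)
# odd voxel count per axis puts a voxel center exactly at the sphere center,
# so the measured SUVmax equals the profile peak
LINEAR_DECAY_SPEC = PhantomSpec(
    radius_mm=20.0,
    profile="linear_decay",
    s_peak=10.0,
    background_suv=0.5,
    spacing_mm=(0.5, 0.5, 0.5),
    extent_mm=(44.5, 44.5, 44.5),
)

UNIFORM_SPEC = PhantomSpec(
    radius_mm=20.0,
    profile="uniform",
    s_peak=10.0,
    background_suv=0.5,
    spacing_mm=(1.0, 1.0, 1.0),
    extent_mm=(48.0, 48.0, 48.0),
)


@pytest.fixture(scope="session")
def linear_decay_volume() -> SuvVolume:
    return make_phantom(LINEAR_DECAY_SPEC)


@pytest.fixture(scope="session")
def uniform_volume() -> SuvVolume:
    return make_phantom(UNIFORM_SPEC)


@pytest.fixture
def whole_box():
    return BoundingBox.whole


@pytest.fixture
def tiny_volume() -> SuvVolume:
    """4x4x4 volume with a 2-voxel hot spot for hand-checkable statistics."""
    values = np.full((4, 4, 4), 0.5)
    values[1, 1, 1] = 4.0
    values[1, 1, 2] = 6.0
    return SuvVolume(values=values, spacing=(1.0, 1.0, 1.0))
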