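import numpy as np
import pytest

from angiomvd import BinaryVolume, VolumeImage
from angiomvd.synthvessel import VesselTreeSpec, generate_tree


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ramp_volume():
    data = np.arange(1000, dtype=np.float32).reshape(10, 10, 10)
    return VolumeImage(data=data, voxel_size_um=9.0)


def straight_tube_mask(shape=(60, 40, 40), axis_len=50, radius=3, start=5):
    """Axis-aligned solid tube along z with a known centerline."""
    from scipy import ndimage

    cz = np.zeros(shape, bool)
    cy, cx = shape[1] // 2, shape[2] // 2
    cz[start : start + axis_len, cy, cx] = True
    dist = ndimage.distance_transform_edt(~cz)
    return (dist <= radius) | cz, cz


@pytest.fixture(scope="session")
def small_phantom():
    """A modest branching phantom reused by several read-only tests."""
    spec = VesselTreeSpec(
        domain_shape=(100, 100, 100),
        n_roots=4,
        branching_prob=0.7,
        segment_length_voxels=(14.0, 20.0),
        radius_root_voxels=2.5,
        tortuosity=0.1,
        noise_sd=4.0,
        seed=42,
        max_generations=2,
    )
    return generate_tree(spec)


@pytest.fixture
def two_tube_mask():
    m1, c1 = straight_tube_mask(shape=(60, 60, 40), axis_len=40, radius=3, start=8)
    m2 = np.zeros_like(m1)
    m2[8:48, 45, 20] = True
    from scipy import ndimage

    m2 = ndimage.distance_transform_edt(~m2) <= 3
    return BinaryVolume(m1 | m2)
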