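import numpy as np
import pytest

from lesionseg.phantoms import PhantomConfig, generate_phantom
from lesionseg.volume_io import SegmentationMask


@pytest.fixture(scope="session")
def small_phantom_config():
    """Desk-scale phantom: small grid, anisotropic spacing, one or two lesions."""
    return PhantomConfig(
        grid_shape=(48, 48, 12),
        spacing=(0.117, 0.117, 1.0),
        brain_semiaxes=(2.4, 2.4, 5.0),
        lesion_count_range=(1, 2),
        lesion_radius_range=(0.6, 1.2),
        lesion_contrast=4.0,
        noise_sigma=1.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_phantom(small_phantom_config):
    return generate_phantom(small_phantom_config)


def make_mask(data, spacing=(1.0, 1.0, 1.0)):
    return SegmentationMask(data=np.asarray(data, dtype=np.uint8), spacing=spacing)


@pytest.fixture
def ball_mask():
    """A solid ~1000-voxel ball, the canonical 'main component' fixture."""
    shape = (32, 32, 32)
    c = np.array([16, 16, 16])
    xx, yy, zz = np.mgrid[: shape[0], : shape[1], : shape[2]]
    r2 = (xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2
    return make_mask(r2 <= 6.2**2)
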