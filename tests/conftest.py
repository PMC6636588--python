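import numpy as np
import pytest

from qmlm.image import Atlas, VolumetricImage
from qmlm.phantom import PhantomSpec, generate_phantom

import pandas as pd


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A reduced phantom grid for fast unit tests."""
    return PhantomSpec(grid_shape=(24, 28, 24), voxel_size_mm=3.0, seed=123)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    """Ten lesion-free subjects on the reduced grid (all channels)."""
    return generate_phantom(small_spec, 10)


@pytest.fixture(scope="session")
def one_subject(small_cohort):
    return small_cohort[0]


def toy_atlas(shape=(12, 12, 12), voxel=2.0):
    """Minimal two-lobe atlas with a ventricle block for filter tests."""
    labels = np.zeros(shape, dtype=np.int16)
    h = shape[0] // 2
    labels[:h] = 1  # frontal left
    labels[h:] = 2  # frontal right
    labels[h - 2:h + 2, h - 2:h + 2, h - 2:h + 2] = 3  # ventricle
    gm = np.zeros(shape, dtype=np.uint8)
    gm[:, :, -3:] = 1  # "cortex" slab at high z
    table = pd.DataFrame([
        {"label": 0, "lobe": "background", "side": "none"},
        {"label": 1, "lobe": "frontal", "side": "left"},
        {"label": 2, "lobe": "frontal", "side": "right"},
        {"label": 3, "lobe": "ventricle", "side": "none"},
    ])
    aff = np.diag([voxel] * 3 + [1.0])
    return Atlas(VolumetricImage(labels, aff), table,
                 gm_mask=VolumetricImage(gm, aff))


@pytest.fixture
def flat_atlas():
    return toy_atlas()


def vol(data, voxel=1.0):
    return VolumetricImage.isotropic(np.asarray(data, dtype=float), voxel)
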