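import numpy as np
import pytest

from boneibr.fesolver import Material, image_to_mesh
from boneibr.image import VoxelImage


@pytest.fixture
def tissue_material():
    return Material(kind="isotropic", E=12_000.0, nu=0.3)


@pytest.fixture
def solid_cube_image():
    """Fully solid 4x4x4 cube, 5.3 mm edge (spacing 1.325 mm)."""
    return VoxelImage(np.ones((4, 4, 4), dtype=np.uint8), spacing=1.325)


@pytest.fixture
def solid_cube_mesh(solid_cube_image, tissue_material):
    return image_to_mesh(solid_cube_image, material=tissue_material)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
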