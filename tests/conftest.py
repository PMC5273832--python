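import numpy as np
import pytest

import tmjmorph as tm
from tmjmorph.phantom import PhantomSpec


@pytest.fixture(scope="session")
def fixture_cohort():
    return tm.load_fixture_cohort()


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free joint phantom at 0.5 mm spacing."""
    spec = PhantomSpec(noise_sd=0.0, seed=0)
    bone, soft, condyle, disc = tm.make_joint_phantom(spec)
    return {"spec": spec, "bone": bone, "soft": soft, "condyle": condyle, "disc": disc}


@pytest.fixture(scope="session")
def noisy_phantom():
    """Joint phantom with Gaussian noise sd 0.05."""
    spec = PhantomSpec(noise_sd=0.05, seed=1)
    bone, soft, condyle, disc = tm.make_joint_phantom(spec)
    return {"spec": spec, "bone": bone, "soft": soft, "condyle": condyle, "disc": disc}


@pytest.fixture(scope="session")
def small_sphere_mesh():
    """Coarse sphere mesh (< 500 vertices) for brute-force oracle checks."""
    return tm.mask_to_mesh(tm.ball_mask(5.0, spacing=1.2))


def two_cube_masks(overlap_slabs: int = 5):
    """Two 10-voxel cubes sharing an overlap_slabs x 10 x 10 slab."""
    a = np.zeros((20, 12, 12), dtype=np.uint8)
    b = np.zeros_like(a)
    a[0:10, 1:11, 1:11] = 1
    b[10 - overlap_slabs : 20 - overlap_slabs, 1:11, 1:11] = 1
    m1 = tm.MaskVolume(a, spacing=(1, 1, 1))
    m2 = tm.MaskVolume(b, spacing=(1, 1, 1))
    return m1, m2
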