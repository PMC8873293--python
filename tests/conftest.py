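import numpy as np
import pytest

import couinaud3d as c3
from couinaud3d.phantom import PhantomConfig, generate_case


def small_config(seed: int = 0, **overrides) -> PhantomConfig:
    """Fast desk-scale phantom: 48 x 48 x 32 at 2 x 2 x 3 mm."""
    kwargs = dict(
        grid_shape=(48, 48, 32),
        spacing_mm=(2.0, 2.0, 3.0),
        liver_radius_mm=(30.0, 25.0, 26.0),
        lesion_diameter_range_mm=(6.0, 14.0),
        seed=seed,
    )
    kwargs.update(overrides)
    return PhantomConfig(**kwargs)


@pytest.fixture(scope="session")
def small_case():
    return generate_case(small_config(seed=3, lesion_count=3))


@pytest.fixture(scope="session")
def default_case():
    """One full-size (96 x 96 x 64) phantom with lesions."""
    return generate_case(PhantomConfig(seed=11, lesion_count=4))


@pytest.fixture(scope="session")
def cube_fixture():
    """Cube 'liver' with landmarks that produce exactly axis-aligned planes.

    The liver is the cube of voxels 4..20 (inclusive) per axis on a 24^3
    1 mm grid.  Landmarks are laid in coordinate planes: MID at x = 11.5,
    RHV at y = 11.5, LHV/LLF at x = 7.5, both portal levels at z = 11.5.
    The venous-ligament curve sits far outside the liver, so S1 is empty.
    """
    from couinaud3d.geometry import LandmarkSet
    from couinaud3d.grid import VolumeGrid

    mask = np.zeros((24, 24, 24), dtype=np.uint8)
    mask[4:21, 4:21, 4:21] = 1
    liver = VolumeGrid(mask, (1.0, 1.0, 1.0))

    lm = LandmarkSet(
        ivc=np.array([[11.5, 5.0, 2.0], [11.5, 5.0, 22.0]]),
        mhv=np.array([[11.5, 8.0, 10.0], [11.5, 14.0, 12.0], [11.5, 11.0, 16.0]]),
        rhv=np.array([[14.0, 11.5, 10.0], [18.0, 11.5, 12.0], [16.0, 11.5, 16.0]]),
        lhv=np.array([[7.5, 9.0, 13.0], [7.5, 14.0, 15.0], [7.5, 11.0, 18.0]]),
        llf=np.array([[7.5, 9.0, 5.0], [7.5, 14.0, 7.0], [7.5, 11.0, 9.0]]),
        gb_vertex=np.array([11.5, 18.0, 4.0]),
        rpv=np.array([16.0, 10.0, 11.5]),
        lpv_sag=np.array([6.0, 10.0, 11.5]),
        vl_fissure=np.array([[-30.0, -30.0, 8.0], [-30.0, -28.0, 14.0]]),
    )
    return liver, lm
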