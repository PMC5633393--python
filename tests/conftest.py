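import numpy as np
import pytest

from trabqtl import PhantomSpec, make_phantom

VOXEL_UM = 10.0


@pytest.fixture(scope="session")
def plate_volume():
    """Plates 100 um thick, 400 um apart, 1 mm cube at 10 um voxels."""
    return make_phantom(
        PhantomSpec(
            "parallel_plates",
            voxel_um=VOXEL_UM,
            shape_voxels=(100, 100, 100),
            plate_thickness_um=100.0,
            plate_spacing_um=400.0,
        )
    )


@pytest.fixture(scope="session")
def ball_volume():
    """Solid ball of radius 200 um, centred on a voxel (odd shape)."""
    return make_phantom(
        PhantomSpec(
            "solid_ball",
            voxel_um=VOXEL_UM,
            shape_voxels=(61, 61, 61),
            ball_radius_um=200.0,
        )
    )


@pytest.fixture(scope="session")
def rod_volume():
    """Square lattice of rods, radius 80 um, pitch 400 um."""
    return make_phantom(
        PhantomSpec(
            "square_lattice_rods",
            voxel_um=VOXEL_UM,
            shape_voxels=(80, 120, 120),
            rod_radius_um=80.0,
            rod_pitch_um=400.0,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20231115)
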