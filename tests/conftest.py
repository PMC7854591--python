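import numpy as np
import pytest

import beadct as bc


@pytest.fixture(scope="session")
def sphere_pack():
    """Five noisy spheres, radii 20-40 um, 4 um gaps, in a 128^3 grid."""
    spec = bc.PhantomSpec(
        shape=(128, 128, 128), n_beads=5, radius_range=(20.0, 40.0),
        min_gap=4.0, seed=7,
    )
    return spec, *bc.gen_sphere_pack(spec)


@pytest.fixture(scope="session")
def porous_pack():
    """Twelve porous ellipsoidal beads with cavities/channels, some touching."""
    spec = bc.PhantomSpec(
        shape=(160, 160, 160), n_beads=12, radius_range=(28.0, 44.0),
        min_gap=4.0, bead_kind="porous_blob",
        pore_spec=bc.PoreSpec(
            n_closed=2, closed_radius_range=(6.0, 10.0),
            n_open=2, open_radius_range=(3.0, 5.0),
        ),
        touching_fraction=0.15, seed=11,
    )
    return spec, *bc.gen_porous_bead_pack(spec)


@pytest.fixture(scope="session")
def porous_segmentation(porous_pack):
    """Porous pack run through the full six-step pipeline."""
    _, vol, truth = porous_pack
    params = bc.SegmentationParams(
        V_small=4000.0, R_p=6.0, R_op=4.0, gaussian_sigma=4.0, variant="porous"
    )
    labels, mask1 = bc.segment_beads(vol, params, "positive")
    return truth, labels, mask1


@pytest.fixture(scope="session")
def noiseless_levels():
    """Noiseless three-level phantom: air 30, liquid 100, bead 200."""
    spec = bc.PhantomSpec(
        shape=(64, 64, 64), n_beads=3, radius_range=(14.0, 22.0),
        min_gap=4.0, intensity_means=(30.0, 100.0, 200.0),
        noise_sigma=0.0, seed=3,
    )
    return bc.gen_sphere_pack(spec)


def digitized_sphere(radius_vox: float, pad: int = 2) -> np.ndarray:
    """Boolean ball: voxel centers within radius of the grid center."""
    n = int(np.ceil(radius_vox)) + pad
    g = np.mgrid[-n : n + 1, -n : n + 1, -n : n + 1]
    return (g[0] ** 2 + g[1] ** 2 + g[2] ** 2) <= radius_vox**2


def digitized_ellipsoid(a: float, b: float, c: float, pad: int = 2) -> np.ndarray:
    n = int(np.ceil(max(a, b, c))) + pad
    g = np.mgrid[-n : n + 1, -n : n + 1, -n : n + 1]
    return (g[0] / a) ** 2 + (g[1] / b) ** 2 + (g[2] / c) ** 2 <= 1.0
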