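"""Canonical phantom benchmarks for end-to-end validation.

These fix the study conditions under which the toolkit's recovery properties
are measured: grid size, bead sizes, pore endowment, contact fraction, noise
level and the segmentation parameters sized to that bead scale.  Both the
test-suite and the reproduction script run the same conditions so reported
numbers refer to one protocol.
"""

from __future__ import annotations

import numpy as np

from .phantoms import PhantomSpec, PoreSpec
from .segment import SegmentationParams

__all__ = [
    "sphere_benchmark_spec",
    "sphere_benchmark_hough",
    "porous_benchmark_spec",
    "porous_benchmark_params",
    "conservation_pack_spec",
]


def sphere_benchmark_spec(seed: int, shape: tuple[int, int, int] = (256, 256, 256)) -> PhantomSpec:
    """Five noisy spheres, radii 20-40 µm, >= 4 µm gaps, 2 µm voxels."""
    return PhantomSpec(
        shape=shape, voxel_size=2.0, n_beads=5,
        radius_range=(20.0, 40.0), min_gap=4.0, seed=seed,
    )


def sphere_benchmark_hough():
    from .sphere_hough import HoughParams

    return HoughParams(R_min=16.0, R_max=44.0)


def porous_benchmark_spec(seed: int, shape: tuple[int, int, int] = (256, 256, 256)) -> PhantomSpec:
    """Fifty porous ellipsoidal beads, ~10% in touching pairs.

    Bead radii 28-44 µm with axis ratios 0.6-1, two interior cavities
    (radius 6-10 µm) and two open channels (throat radius 3-5 µm) per bead.
    """
    return PhantomSpec(
        shape=shape, voxel_size=2.0, n_beads=50,
        radius_range=(28.0, 44.0), min_gap=4.0,
        bead_kind="porous_blob",
        pore_spec=PoreSpec(
            n_closed=2, closed_radius_range=(6.0, 10.0),
            n_open=2, open_radius_range=(3.0, 5.0),
        ),
        touching_fraction=0.10, seed=seed,
    )


def porous_benchmark_params() -> SegmentationParams:
    """Segmentation settings sized to the porous benchmark bead scale.

    R_p = 6 µm exceeds every channel throat radius (3-5 µm) so all open
    pores seal; the watershed smoothing of 6 voxels matches beads of 14-22
    voxel radius.
    """
    return SegmentationParams(
        V_small=4000.0, R_p=6.0, R_op=4.0, gaussian_sigma=6.0, variant="porous"
    )


def conservation_pack_spec(seed: int) -> PhantomSpec:
    """Fifty small porous beads for the volume-conservation sweep."""
    return PhantomSpec(
        shape=(192, 192, 192), voxel_size=2.0, n_beads=50,
        radius_range=(12.0, 20.0), min_gap=4.0,
        bead_kind="porous_blob",
        pore_spec=PoreSpec(
            n_closed=1, closed_radius_range=(4.0, 6.0),
            n_open=1, open_radius_range=(3.0, 4.0),
        ),
        seed=seed,
    )
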