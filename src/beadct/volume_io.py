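"""Volume containers, TIFF stack I/O and pre-analysis housekeeping.

Arrays are stored in ``(z, y, x)`` index order (slice index first, matching
multi-page TIFF layout); all public physical quantities are in µm, µm² and
µm³.  Voxels are isotropic: one ``voxel_size`` in µm per volume.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "Volume3D",
    "read_stack",
    "write_stack",
    "circular_roi",
    "downsample",
    "write_morphometrics",
    "read_morphometrics",
]


@dataclass
class Volume3D:
    """A 3D grayscale intensity grid with an isotropic voxel size.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Intensities. 8- or 16-bit unsigned integers for CT-like data, but any
        scalar dtype is accepted.
    voxel_size : float
        Edge length of one voxel in µm (default 2.0, a typical micro-CT
        reconstruction resolution for microcarrier samples).
    provenance : str
        Free-text source tag (file path, phantom spec, ...).
    """

    data: np.ndarray
    voxel_size: float = 2.0
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("volume must be a 3D grid with all dimensions >= 1")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        return float(self.voxel_size) ** 3


def read_stack(path: str, voxel_size: float) -> Volume3D:
    """Read a volume from a multi-page TIFF or a directory of TIFF slices.

    Slices in a directory are taken in lexicographic filename order and map to
    the first (z) axis. Gray values of 8/16-bit input are preserved exactly.
    """
    if os.path.isdir(path):
        names = sorted(
            f for f in os.listdir(path) if f.lower().endswith((".tif", ".tiff"))
        )
        if not names:
            raise ValueError(f"no TIFF slices found in directory {path!r}")
        slices = []
        shape0 = None
        for name in names:
            sl = tifffile.imread(os.path.join(path, name))
            if sl.ndim != 2:
                raise ValueError(f"slice {name!r} is not a single 2D page")
            if shape0 is None:
                shape0 = sl.shape
            elif sl.shape != shape0:
                raise ValueError(
                    f"slice {name!r} has shape {sl.shape}, expected {shape0}"
                )
            slices.append(sl)
        data = np.stack(slices, axis=0)
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ValueError(f"{path!r} does not contain a 2D/3D grayscale stack")
    if data.dtype.kind not in "uif":
        raise ValueError(f"unsupported sample format {data.dtype}")
    return Volume3D(data, voxel_size=voxel_size, provenance=str(path))


def write_stack(volume: Volume3D | np.ndarray, path: str) -> None:
    """Write a volume (or raw label/mask array) as a multi-page TIFF."""
    data = volume.data if isinstance(volume, Volume3D) else np.asarray(volume)
    if data.dtype == bool:
        data = data.astype(np.uint8) * 255
    tifffile.imwrite(path, data)


def circular_roi(
    volume: Volume3D,
    center_xy: tuple[float, float],
    radius: float,
    fill: float = 0,
) -> Volume3D:
    """Clear everything outside a circular in-slice region of interest.

    Emulates the manual step of drawing circular ROIs to remove the sample
    container (e.g. an Eppendorf tube wall) from every slice: voxels whose
    in-slice center distance from ``center_xy`` (in voxels, (x, y)) exceeds
    ``radius`` (voxels) are set to ``fill`` on all slices.  A voxel is inside
    if its center distance is <= radius.
    """
    if not radius > 0:
        raise ValueError("ROI radius must be > 0")
    cx, cy = center_xy
    nz, ny, nx = volume.shape
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    outside = (xx - cx) ** 2 + (yy - cy) ** 2 > radius**2
    data = volume.data.copy()
    data[:, outside] = fill
    return replace(volume, data=data)


def downsample(volume: Volume3D, factor: int) -> Volume3D:
    """Resize by an integer factor using block averaging.

    Output dimensions are floored to a multiple of ``factor``; the voxel size
    is multiplied accordingly, so physical sizes are preserved in expectation.
    Block-mean (rather than decimation) keeps the three-peak histogram
    structure the binarizer relies on.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("downsample factor must be an integer >= 1")
    factor = int(factor)
    if factor == 1:
        return volume
    nz, ny, nx = (d // factor for d in volume.shape)
    if min(nz, ny, nx) < 1:
        raise ValueError("volume too small for the requested factor")
    d = volume.data[: nz * factor, : ny * factor, : nx * factor].astype(np.float64)
    d = d.reshape(nz, factor, ny, factor, nx, factor).mean(axis=(1, 3, 5))
    if volume.data.dtype.kind == "u":
        d = np.round(d).astype(volume.data.dtype)
    return Volume3D(
        d,
        voxel_size=volume.voxel_size * factor,
        provenance=volume.provenance + f" [downsampled x{factor}]",
    )


# stable CSV schema for per-bead morphometrics; alpha columns are appended as
# alpha_area_um2_at_<cellsize> in increasing cell-size order ('inf' last)
_BASE_COLUMNS = [
    "bead_id",
    "touches_border",
    "equivalent_diameter_um",
    "principal_axis_1_um",
    "principal_axis_2_um",
    "principal_axis_3_um",
    "bead_volume_um3",
    "convex_hull_volume_um3",
    "open_pore_volume_um3",
    "closed_pore_volume_um3",
    "porosity",
    "convex_surface_area_um2",
]


def _alpha_key(cell_size: float) -> str:
    if np.isinf(cell_size):
        return "alpha_area_um2_at_inf"
    return f"alpha_area_um2_at_{cell_size:g}"


def write_morphometrics(records, path: str) -> None:
    """Write per-bead morphometrics to CSV, one row per bead.

    All records must share one alpha-profile cell-size grid; floats are
    written at full precision. An empty record list yields a header-only file.
    """
    records = list(records)
    alpha_sizes: list[float] = []
    if records:
        alpha_sizes = sorted(records[0].alpha_profile.keys())
        for r in records:
            if sorted(r.alpha_profile.keys()) != alpha_sizes:
                raise ValueError(
                    "records have differing alpha-profile cell-size grids; "
                    "a common grid is required for one CSV"
                )
    rows = []
    for r in records:
        row = {
            "bead_id": r.bead_id,
            "touches_border": bool(r.touches_border),
            "equivalent_diameter_um": r.equivalent_diameter,
            "principal_axis_1_um": r.principal_axis_lengths[0],
            "principal_axis_2_um": r.principal_axis_lengths[1],
            "principal_axis_3_um": r.principal_axis_lengths[2],
            "bead_volume_um3": r.bead_volume,
            "convex_hull_volume_um3": r.convex_hull_volume,
            "open_pore_volume_um3": r.open_pore_volume,
            "closed_pore_volume_um3": r.closed_pore_volume,
            "porosity": r.porosity,
            "convex_surface_area_um2": r.convex_surface_area,
        }
        for cs in alpha_sizes:
            row[_alpha_key(cs)] = r.alpha_profile[cs]
        rows.append(row)
    cols = _BASE_COLUMNS + [_alpha_key(cs) for cs in alpha_sizes]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format="%.17g")


def read_morphometrics(path: str) -> pd.DataFrame:
    """Read a morphometrics CSV back into a DataFrame (floats bit-exact)."""
    return pd.read_csv(path, float_precision="round_trip")
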