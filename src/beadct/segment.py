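"""Single-bead segmentation of touching, porous or concave microcarriers.

The pipeline isolates individual beads from a binarized contrast-enhanced CT
volume in six steps: (1) three-class Otsu binarization with staining-aware
foreground selection, (2) removal of small noise objects (18-connectivity),
(3–5) sealing of open pores by a background distance-transform threshold, a
morphological opening, clearing of isolated pore objects and a dilation back
to the bead boundary, and (6) splitting of touching beads with a watershed on
the Gaussian-smoothed Euclidean distance transform.

Non-porous beads imaged with negative staining use a variant: the pore
sealing steps are skipped and replaced by a morphological closing plus
removal of small background ("black") components, which suppresses noise
speckle inherent to the negative contrast regime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.segmentation import watershed

from ._geometry import ball_ops
from .binarize import multi_otsu, select_foreground
from .volume_io import Volume3D

__all__ = [
    "SegmentationParams",
    "LabelVolume",
    "remove_small_objects",
    "seal_open_pores",
    "split_touching_beads",
    "segment_beads",
]

# 18-connectivity: faces + edges
_CONN18 = ndimage.generate_binary_structure(3, 2)
_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SegmentationParams:
    """Tunables of the segmentation pipeline, physical units in µm.

    V_small — volume cutoff (µm³) below which foreground objects are treated
    as noise; R_p — half the largest pore-throat thickness to seal (µm);
    R_op — radius of the opening that disconnects remaining pores from the
    background (µm); R_cl — closing radius for the non-porous negative-stain
    variant (µm); black_cutoff — volume cutoff for small background
    components in that variant (defaults to V_small); gaussian_sigma —
    standard deviation, in voxels of the working grid, of the Gaussian filter
    applied to the distance transform before the watershed.

    These are per-dataset acquisition-dependent settings with no universal
    values; the defaults are only sized for ~2 µm voxels and 100–300 µm
    beads.
    """

    V_small: float = 0.0
    R_p: float = 0.0
    R_op: float = 0.0
    R_cl: float = 0.0
    black_cutoff: float | None = None
    gaussian_sigma: float = 7.0
    object_connectivity: int = 18
    variant: str = "porous"  # porous | nonporous_negative

    def __post_init__(self) -> None:
        if min(self.V_small, self.R_p, self.R_op, self.R_cl) < 0:
            raise ValueError("radii and volume cutoffs must be >= 0")
        if not self.gaussian_sigma > 0:
            raise ValueError("gaussian_sigma must be > 0")
        if self.variant not in ("porous", "nonporous_negative"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.object_connectivity != 18:
            raise ValueError("only 18-connectivity objects are supported")


@dataclass
class LabelVolume:
    """Per-voxel bead labels (0 = background) on the source grid."""

    labels: np.ndarray  # int32
    voxel_size: float
    border_labels: frozenset[int] = field(default_factory=frozenset)

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    def touches_border(self, label: int) -> bool:
        return label in self.border_labels


def remove_small_objects(
    mask: np.ndarray, V_small: float, voxel_size: float = 1.0, connectivity: int = 18
) -> np.ndarray:
    """Drop foreground components with volume < V_small (µm³).

    Components are 18-connected by default; surviving voxels are unchanged.
    """
    if V_small <= 0:
        return mask.copy()
    struct = {6: ndimage.generate_binary_structure(3, 1), 18: _CONN18, 26: _CONN26}[
        connectivity
    ]
    lab, n = ndimage.label(mask, structure=struct)
    if n == 0:
        return mask.copy()
    counts = np.bincount(lab.ravel())
    keep = counts * voxel_size**3 >= V_small
    keep[0] = False
    return keep[lab]


def _clear_border_complement(mask: np.ndarray) -> np.ndarray:
    """Components of ``mask`` not touching the volume border (26-conn)."""
    lab, n = ndimage.label(mask, structure=_CONN26)
    if n == 0:
        return np.zeros_like(mask)
    border_ids = np.unique(
        np.concatenate(
            [
                lab[0].ravel(), lab[-1].ravel(),
                lab[:, 0].ravel(), lab[:, -1].ravel(),
                lab[:, :, 0].ravel(), lab[:, :, -1].ravel(),
            ]
        )
    )
    interior = ~np.isin(np.arange(n + 1), border_ids)
    interior[0] = False
    return interior[lab]


def seal_open_pores(mask1: np.ndarray, R_p: float, R_op: float, voxel_size: float = 1.0) -> np.ndarray:
    """Seal open pores narrower than the configured throat size.

    Starting from the denoised bead mask (MASK1): the Euclidean distance
    transform of the background is thresholded at > R_p, disconnecting pore
    channels of half-thickness < R_p from the background (MASK2); an opening
    with a spherical element of radius R_op removes remaining thin background
    tendrils (MASK3); background components not touching the volume border —
    the isolated pores — are cleared; and the surviving true background is
    dilated by R_p back to the bead boundary (MASK4).  The returned mask is
    the complement of MASK4: beads with their open pores sealed (closed pores
    are filled as well, by construction).
    """
    rp = R_p / voxel_size
    rop = R_op / voxel_size
    bg_dist = ndimage.distance_transform_edt(~mask1)
    mask2 = bg_dist > rp
    mask3 = ball_ops.open(mask2, rop)
    pores = _clear_border_complement(mask3)
    background = mask3 & ~pores
    mask4 = ball_ops.dilate(background, rp)
    return ~mask4


def split_touching_beads(
    sealed: np.ndarray, gaussian_sigma: float = 7.0, voxel_size: float = 1.0
) -> LabelVolume:
    """Split touching beads by watershed on the distance transform.

    The Euclidean distance transform of the sealed mask is Gaussian-filtered
    with ``gaussian_sigma`` (voxels) and its local maxima become the bead
    markers — the smoothing merges the spurious maxima that digitization
    noise creates, which is what keeps single beads from oversplitting.
    Flooding then runs on the negated *unsmoothed* distance transform so the
    cut between touching beads falls on the true neck (the smoothed surface
    displaces it by up to ~sigma voxels, shaving caps off beads).  Basins
    are flooded jointly, so no voxel is left on a watershed line.
    """
    if not sealed.any():
        return LabelVolume(np.zeros(sealed.shape, np.int32), voxel_size)
    dist = ndimage.distance_transform_edt(sealed)
    smooth = ndimage.gaussian_filter(dist, sigma=gaussian_sigma)
    peaks = (smooth == ndimage.maximum_filter(smooth, size=3)) & sealed & (smooth > 1.0)
    markers, n_markers = ndimage.label(peaks, structure=_CONN26)
    if n_markers == 0:
        labels, _ = ndimage.label(sealed, structure=_CONN18)
    else:
        labels = watershed(-dist, markers=markers, mask=sealed, watershed_line=False)
    return _renumber(labels.astype(np.int32), voxel_size)


def _renumber(labels: np.ndarray, voxel_size: float) -> LabelVolume:
    """Renumber labels consecutively in first-appearance scan order."""
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    flat = labels.ravel()
    nz = np.flatnonzero(flat)
    order = nz[np.unique(flat[nz], return_index=True)[1]]
    for new_id, pos in enumerate(sorted(order), start=1):
        lut[flat[pos]] = new_id
    out = lut[labels]
    border_ids = np.unique(
        np.concatenate(
            [
                out[0].ravel(), out[-1].ravel(),
                out[:, 0].ravel(), out[:, -1].ravel(),
                out[:, :, 0].ravel(), out[:, :, -1].ravel(),
            ]
        )
    )
    border = frozenset(int(b) for b in border_ids if b > 0)
    return LabelVolume(out, voxel_size, border_labels=border)


def _fill_small_background(mask: np.ndarray, cutoff: float, voxel_size: float) -> np.ndarray:
    """Fill background components with volume < cutoff (µm³)."""
    if cutoff <= 0:
        return mask
    lab, n = ndimage.label(~mask, structure=_CONN26)
    if n == 0:
        return mask
    counts = np.bincount(lab.ravel())
    fill = counts * voxel_size**3 < cutoff
    fill[0] = False
    return mask | fill[lab]


def segment_beads(
    volume: Volume3D, params: SegmentationParams, staining: str
) -> tuple[LabelVolume, np.ndarray]:
    """Run the full segmentation pipeline on a grayscale volume.

    Returns the bead label volume (over the pore-sealed foreground) and the
    binarized, denoised foreground mask (MASK1) — per-bead morphometrics are
    computed on MASK1 restricted to each label, so pores reappear in the
    per-bead images.  Beads touching the volume border are recorded in
    ``LabelVolume.border_labels``.
    """
    vs = volume.voxel_size
    otsu = multi_otsu(volume)
    fg = select_foreground(volume, otsu, staining)
    mask1 = remove_small_objects(fg, params.V_small, voxel_size=vs)

    if params.variant == "porous":
        if params.R_cl > 0:
            warnings.warn("R_cl is ignored by the porous variant", stacklevel=2)
        sealed = seal_open_pores(mask1, params.R_p, params.R_op, voxel_size=vs)
    else:
        if params.R_p > 0 or params.R_op > 0:
            warnings.warn(
                "R_p/R_op are ignored by the nonporous_negative variant",
                stacklevel=2,
            )
        closed = ball_ops.close(mask1, params.R_cl / vs) if params.R_cl > 0 else mask1
        cutoff = params.black_cutoff if params.black_cutoff is not None else params.V_small
        sealed = _fill_small_background(closed, cutoff, vs)
        mask1 = sealed  # nonporous beads: the cleaned mask is the bead image

    label_vol = split_touching_beads(sealed, params.gaussian_sigma, voxel_size=vs)
    return label_vol, mask1
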