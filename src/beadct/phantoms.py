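"""Synthetic micro-CT-like bead phantoms with exhaustive voxel ground truth.

No raw CT volumes of microcarrier samples are publicly deposited, so every
downstream stage of this toolkit is validated on phantoms that emulate the
salient features of contrast-enhanced CT of hydrated beads:

* a three-peak gray-level histogram (air, staining solution, bead matrix)
  with additive Gaussian noise, in both positive- and negative-staining
  contrast regimes;
* beads suspended inside a cylindrical "tube" of liquid surrounded by air;
* spherical beads (polystyrene/dextran carriers) or randomized ellipsoidal
  blobs with internal cavities (closed pores), surface channels (open pores)
  or surface dents (concave carriers);
* optional touching/overlapping bead pairs to exercise watershed splitting.

Ground truth (per-voxel labels, centers, radii, pore volumes) is recorded at
generation time, with pore classification done by connected-component
analysis against the background, so segmentation and morphometric accuracy
can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from ._geometry import hull_image
from .volume_io import Volume3D

__all__ = [
    "PoreSpec",
    "PhantomSpec",
    "PhantomTruth",
    "PackingError",
    "gen_sphere_pack",
    "gen_porous_bead_pack",
    "apply_staining",
]

_RETRY_BUDGET = 10_000  # rejection-sampling retries per bead


class PackingError(RuntimeError):
    """Raised when a bead cannot be placed within the retry budget."""


@dataclass
class PoreSpec:
    """Per-bead pore endowment.

    ``n_closed`` interior spherical cavities with radii drawn from
    ``closed_radius_range`` (µm) and ``n_open`` cylindrical channels from the
    bead interior to the exterior with radii from ``open_radius_range`` (µm).
    For concave blobs the "open" entries are spherical surface dents instead
    of through-channels.
    """

    n_closed: int = 2
    closed_radius_range: tuple[float, float] = (6.0, 10.0)
    n_open: int = 2
    open_radius_range: tuple[float, float] = (4.0, 6.0)


@dataclass
class PhantomSpec:
    """Parameters of one synthetic bead volume.

    Defaults describe the study conditions used throughout the test-suite:
    2 µm voxels, bead radii 20–40 µm, 4 µm minimum inter-bead gap, 8-bit
    gray range with peak separations ~ 80–110 gray levels and noise sigma
    8 gray levels (well below a third of the smallest separation, so the
    three-peak valley structure survives).
    """

    shape: tuple[int, int, int] = (128, 128, 128)  # (z, y, x) voxels
    voxel_size: float = 2.0  # µm
    n_beads: int = 20
    radius_range: tuple[float, float] = (20.0, 40.0)  # µm
    bead_kind: str = "sphere"  # sphere | porous_blob | concave_blob
    pore_spec: PoreSpec = field(default_factory=PoreSpec)
    min_gap: float = 4.0  # µm; negative permits overlap
    touching_fraction: float = 0.0  # fraction of beads placed touching a partner
    staining: str = "positive"
    intensity_means: tuple[float, float, float] = (20.0, 100.0, 210.0)  # air, liquid, bead
    noise_sigma: float = 8.0  # gray levels
    seed: int = 0

    def __post_init__(self) -> None:
        rmin, rmax = self.radius_range
        if not (0 < rmin <= rmax):
            raise ValueError("radius_range must satisfy 0 < min <= max")
        if self.bead_kind not in ("sphere", "porous_blob", "concave_blob"):
            raise ValueError(f"unknown bead_kind {self.bead_kind!r}")
        if self.staining not in ("positive", "negative"):
            raise ValueError(f"unknown staining {self.staining!r}")
        if len(set(self.intensity_means)) != 3:
            raise ValueError("degenerate contrast: intensity means must be distinct")


@dataclass
class PhantomTruth:
    """Exhaustive ground truth of a generated phantom.

    Coordinates are array-ordered (z, y, x); centers in µm.  Volumes are
    voxel counts of the truth label volume (multiply by ``voxel_size**3``
    for µm³).  ``media_mask`` marks the liquid region used for staining.
    """

    label_volume: np.ndarray  # int32, 0 = background
    voxel_size: float
    centers_um: np.ndarray  # (n, 3) µm, (z, y, x) order
    radii_um: np.ndarray  # (n,) nominal radius (max semi-axis for blobs)
    semi_axes_um: np.ndarray  # (n, 3) µm, = radius for spheres
    volume_vox: np.ndarray  # (n,)
    closed_pore_vox: np.ndarray
    open_pore_vox: np.ndarray
    hull_vox: np.ndarray
    touches_border: np.ndarray  # (n,) bool
    media_mask: np.ndarray  # bool, liquid region (background only rendered as liquid here)

    @property
    def n_beads(self) -> int:
        return len(self.centers_um)

    def porosity(self) -> np.ndarray:
        """True porosity per bead, 1 - V_bead / V_hull."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return 1.0 - self.volume_vox / self.hull_vox


def _bead_rngs(seed: int, n: int) -> list[np.random.Generator]:
    # one stream per bead index so adding beads never perturbs earlier ones
    return [np.random.default_rng([int(seed), k]) for k in range(n)]


def _tube(shape: tuple[int, int, int]) -> tuple[float, float, float]:
    """Liquid cylinder (axis along z): center (cy, cx) and radius, voxels."""
    nz, ny, nx = shape
    return (ny - 1) / 2.0, (nx - 1) / 2.0, 0.47 * min(ny, nx)


def _place_beads(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample bead centers and nominal radii (voxel units)."""
    nz, ny, nx = spec.shape
    vs = spec.voxel_size
    rmin_v, rmax_v = (r / vs for r in spec.radius_range)
    gap_v = spec.min_gap / vs
    cy, cx, tube_r = _tube(spec.shape)
    rngs = _bead_rngs(spec.seed, spec.n_beads)

    n_touch = int(round(spec.touching_fraction * spec.n_beads))
    touch_idx = set(range(1, 2 * n_touch, 2)) if n_touch else set()

    centers = np.zeros((spec.n_beads, 3))
    radii = np.zeros(spec.n_beads)
    for i in range(spec.n_beads):
        rng = rngs[i]
        placed = False
        for _ in range(_RETRY_BUDGET):
            r = rng.uniform(rmin_v, rmax_v)
            if i in touch_idx and i > 0:
                # place touching the previous bead with a thin-neck overlap
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                depth = 0.25 * min(r, radii[i - 1])
                c = centers[i - 1] + direction * (r + radii[i - 1] - depth)
                partner = i - 1
            else:
                margin = r + 1
                c = np.array(
                    [
                        rng.uniform(margin, nz - 1 - margin),
                        rng.uniform(cy - tube_r, cy + tube_r),
                        rng.uniform(cx - tube_r, cx + tube_r),
                    ]
                )
                partner = None
            # inside the liquid tube with margin
            if np.hypot(c[1] - cy, c[2] - cx) > tube_r - r - 1:
                continue
            if not (r + 1 <= c[0] <= nz - 1 - r - 1):
                continue
            ok = True
            for j in range(i):
                if j == partner:
                    continue
                need = r + radii[j] + max(gap_v, 0.0)
                if np.linalg.norm(c - centers[j]) < need:
                    ok = False
                    break
            if ok:
                centers[i] = c
                radii[i] = r
                placed = True
                break
        if not placed:
            raise PackingError(
                f"could not place bead {i} (radius ~{rmin_v * vs:.0f}-"
                f"{rmax_v * vs:.0f} µm) within {_RETRY_BUDGET} retries"
            )
    return centers, radii


def _carve_and_label(spec: PhantomSpec, centers: np.ndarray, radii: np.ndarray):
    """Voxelize beads (overlaps resolved by depth), carve pores, build truth."""
    nz, ny, nx = spec.shape
    vs = spec.voxel_size
    labels = np.zeros(spec.shape, dtype=np.int32)
    depth = np.full(spec.shape, -np.inf, dtype=np.float32)
    semi_axes = np.zeros((spec.n_beads, 3))
    rotations = []
    rngs = _bead_rngs(spec.seed + 1_000_003, spec.n_beads)  # shape/pore stream

    for i in range(spec.n_beads):
        rng = rngs[i]
        c, r = centers[i], radii[i]
        if spec.bead_kind == "sphere":
            axes = np.array([r, r, r])
            rot = np.eye(3)
        else:
            ratios = rng.uniform(0.6, 1.0, size=2)
            axes = np.array([r, r * ratios[0], r * ratios[1]])
            rot = Rotation.random(rng=rng).as_matrix()
        semi_axes[i] = axes
        rotations.append(rot)

        lo = np.maximum(np.floor(c - r - 1).astype(int), 0)
        hi = np.minimum(np.ceil(c + r + 2).astype(int), spec.shape)
        grids = np.meshgrid(*[np.arange(lo[k], hi[k]) for k in range(3)], indexing="ij")
        pts = np.stack([g - c[k] for k, g in enumerate(grids)], axis=-1)
        local = pts @ rot  # rotate into the ellipsoid frame
        q = np.sqrt(((local / axes) ** 2).sum(axis=-1))
        bead_depth = ((1.0 - q) * axes.min()).astype(np.float32)
        sub = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
        win = (bead_depth >= 0) & (bead_depth > depth[sub])
        depth[sub][win] = bead_depth[win]
        labels[sub][win] = i + 1

    # carve pores (cavities / channels / dents) as background
    if spec.bead_kind in ("porous_blob", "concave_blob"):
        ps = spec.pore_spec
        for i in range(spec.n_beads):
            rng = rngs[i]
            c = centers[i]
            axes = semi_axes[i]
            rot = rotations[i]
            min_ax = axes.min()
            for _ in range(ps.n_closed):
                pr = rng.uniform(*ps.closed_radius_range) / vs
                if pr >= min_ax:
                    raise ValueError("pore radius must be smaller than the bead radius")
                # shrink the cavity so it stays strictly interior to small beads
                pr = min(pr, min_ax - 4.0)
                if pr < 1.5:
                    continue
                max_off = min_ax - pr - 2.5
                off = rng.normal(size=3)
                off *= rng.uniform(0, max_off) / np.linalg.norm(off)
                _carve_sphere(labels, c + off, pr, only_label=i + 1)
            for _ in range(ps.n_open):
                pr = rng.uniform(*ps.open_radius_range) / vs
                if pr >= min_ax:
                    raise ValueError("pore radius must be smaller than the bead radius")
                direction = rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                if spec.bead_kind == "porous_blob":
                    # channels start off-center so interior cavities usually
                    # survive as closed pores
                    _carve_cylinder(
                        labels, c, direction, pr, axes.max() + 2, i + 1,
                        t_start=0.45 * min_ax,
                    )
                else:
                    # concave dent: sphere bite centered on the surface
                    surf = c + direction * _ellipsoid_extent(direction, axes, rot)
                    _carve_sphere(labels, surf, 2.5 * pr, only_label=i + 1)
    return labels, semi_axes


def _ellipsoid_extent(direction: np.ndarray, axes: np.ndarray, rot: np.ndarray) -> float:
    local = direction @ rot
    return 1.0 / np.sqrt(((local / axes) ** 2).sum())


def _carve_sphere(labels, center, radius, only_label):
    lo = np.maximum(np.floor(center - radius - 1).astype(int), 0)
    hi = np.minimum(np.ceil(center + radius + 2).astype(int), labels.shape)
    if (hi <= lo).any():
        return
    grids = np.meshgrid(*[np.arange(lo[k], hi[k]) for k in range(3)], indexing="ij")
    d2 = sum((g - center[k]) ** 2 for k, g in enumerate(grids))
    sub = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
    hit = (d2 <= radius**2) & (labels[sub] == only_label)
    labels[sub][hit] = 0


def _carve_cylinder(labels, center, direction, radius, length, only_label, t_start=0.0):
    ext = length + radius + 1
    lo = np.maximum(np.floor(center - ext).astype(int), 0)
    hi = np.minimum(np.ceil(center + ext + 1).astype(int), labels.shape)
    grids = np.meshgrid(*[np.arange(lo[k], hi[k]) for k in range(3)], indexing="ij")
    pts = np.stack([g - center[k] for k, g in enumerate(grids)], axis=-1)
    t = pts @ direction
    radial = np.sqrt(np.maximum((pts**2).sum(axis=-1) - t**2, 0.0))
    sub = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
    hit = (radial <= radius) & (t >= t_start) & (t <= length) & (labels[sub] == only_label)
    labels[sub][hit] = 0


_FULL_CONN = np.ones((3, 3, 3), dtype=bool)


def _truth_pores(labels: np.ndarray, n_beads: int):
    """Classify per-bead pore voxels by connectivity against the background."""
    vol = np.zeros(n_beads, dtype=np.int64)
    closed = np.zeros(n_beads, dtype=np.int64)
    opened = np.zeros(n_beads, dtype=np.int64)
    hullv = np.zeros(n_beads, dtype=np.int64)
    border = np.zeros(n_beads, dtype=bool)
    objects = ndimage.find_objects(labels)
    for i in range(n_beads):
        orig = objects[i] if i < len(objects) else None
        if orig is None:
            continue
        border[i] = any(
            s.start == 0 or s.stop == labels.shape[k] for k, s in enumerate(orig)
        )
        sl = tuple(
            slice(max(s.start - 1, 0), min(s.stop + 1, labels.shape[k]))
            for k, s in enumerate(orig)
        )
        bead = labels[sl] == i + 1
        bead = np.pad(bead, 1)  # guarantee a background border for clearing
        vol[i] = int(bead.sum())
        inv_lab, _ = ndimage.label(~bead, structure=_FULL_CONN)
        border_ids = np.unique(
            np.concatenate(
                [
                    inv_lab[0].ravel(), inv_lab[-1].ravel(),
                    inv_lab[:, 0].ravel(), inv_lab[:, -1].ravel(),
                    inv_lab[:, :, 0].ravel(), inv_lab[:, :, -1].ravel(),
                ]
            )
        )
        closed_mask = ~bead & ~np.isin(inv_lab, border_ids)
        closed[i] = int(closed_mask.sum())
        hull = hull_image(bead)
        hullv[i] = int(hull.sum())
        opened[i] = int((hull & ~bead & ~closed_mask).sum())
    return vol, closed, opened, hullv, border


def _render(spec: PhantomSpec, labels: np.ndarray, seed_offset: int = 2_000_003):
    """Grayscale rendering of a truth labeling (tube of liquid in air)."""
    cy, cx, tube_r = _tube(spec.shape)
    ny, nx = spec.shape[1], spec.shape[2]
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    media = np.broadcast_to(
        (yy - cy) ** 2 + (xx - cx) ** 2 <= tube_r**2, spec.shape
    ).copy()
    air_i, liq_i, bead_i = spec.intensity_means
    if spec.staining == "positive" and not (air_i < liq_i < bead_i):
        raise ValueError("positive staining needs air < liquid < bead intensities")
    if spec.staining == "negative" and not (air_i < bead_i < liq_i):
        raise ValueError("negative staining needs air < bead < liquid intensities")
    gray = np.full(spec.shape, air_i, dtype=np.float64)
    gray[media] = liq_i
    gray[labels > 0] = bead_i
    if spec.noise_sigma > 0:
        rng = np.random.default_rng([int(spec.seed), seed_offset])
        gray += rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    gray = np.clip(np.round(gray), 0, 255).astype(np.uint8)
    return gray, media


def _generate(spec: PhantomSpec) -> tuple[Volume3D, PhantomTruth]:
    vs = spec.voxel_size
    if spec.n_beads == 0:
        labels = np.zeros(spec.shape, dtype=np.int32)
        centers = np.zeros((0, 3))
        radii = np.zeros(0)
        semi_axes = np.zeros((0, 3))
    else:
        centers, radii = _place_beads(spec)
        labels, semi_axes = _carve_and_label(spec, centers, radii)
    vol, closed, opened, hullv, border = _truth_pores(labels, spec.n_beads)
    gray, media = _render(spec, labels)
    truth = PhantomTruth(
        label_volume=labels,
        voxel_size=vs,
        centers_um=centers * vs,
        radii_um=radii * vs,
        semi_axes_um=semi_axes * vs,
        volume_vox=vol,
        closed_pore_vox=closed,
        open_pore_vox=opened,
        hull_vox=hullv,
        touches_border=border,
        media_mask=media,
    )
    volume = Volume3D(gray, voxel_size=vs, provenance=f"phantom(seed={spec.seed})")
    return volume, truth


def gen_sphere_pack(spec: PhantomSpec) -> tuple[Volume3D, PhantomTruth]:
    """Generate a pack of non-overlapping (unless requested) digitized spheres.

    The returned grayscale volume has three histogram modes at the configured
    intensity means plus clipped Gaussian noise; the truth carries exact
    centers and radii.  Identical spec and seed reproduce the volume
    bit-for-bit.
    """
    if spec.bead_kind != "sphere":
        raise ValueError("gen_sphere_pack requires bead_kind='sphere'")
    return _generate(spec)


def gen_porous_bead_pack(spec: PhantomSpec) -> tuple[Volume3D, PhantomTruth]:
    """Generate randomized ellipsoidal beads with carved pores.

    ``porous_blob`` beads get interior cavities (closed pores) and cylindrical
    channels to the surface (open pores); ``concave_blob`` beads get spherical
    surface dents instead of channels.  Truth pore volumes are classified by
    connected-component analysis against the background.
    """
    if spec.bead_kind not in ("porous_blob", "concave_blob"):
        raise ValueError("gen_porous_bead_pack requires a blob bead_kind")
    return _generate(spec)


def apply_staining(
    volume: Volume3D,
    truth: PhantomTruth,
    staining: str,
    intensity_means: tuple[float, float, float],
    noise_sigma: float,
    seed: int,
) -> Volume3D:
    """Re-render a phantom under a different contrast regime.

    ``intensity_means`` are the (air, liquid, bead) gray levels; positive
    staining requires air < liquid < bead, negative air < bead < liquid.
    Noise is additive Gaussian, clipped to the 8-bit range.
    """
    spec = PhantomSpec(
        shape=truth.label_volume.shape,
        voxel_size=truth.voxel_size,
        n_beads=truth.n_beads,
        staining=staining,
        intensity_means=tuple(intensity_means),
        noise_sigma=noise_sigma,
        seed=seed,
    )
    gray, _ = _render(spec, truth.label_volume)
    return Volume3D(
        gray, voxel_size=truth.voxel_size, provenance=volume.provenance + " [restained]"
    )
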