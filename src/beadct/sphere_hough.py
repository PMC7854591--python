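"""Spherical bead detection by a 3D Hough transform.

Edge voxels (high gradient magnitude) vote along their ±gradient direction
at every candidate radius between R_min and R_max; vote maps are normalized
by the theoretical shell support (∝ r²) so the accumulator score is a
support fraction comparable across radii.  Candidate centers are local
accumulator maxima above a threshold, deduplicated by greedy non-maximum
suppression, and each detection is refined to sub-voxel precision by a
least-squares sphere fit to the full-resolution edge voxels on its shell.

Detection runs on a block-averaged working grid (configurable factor) for
speed; all outputs are in µm on the original grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import Volume3D, downsample

__all__ = ["SphereFit", "HoughParams", "detect_spheres", "sphere_metrics", "build_shell_mask"]


@dataclass(frozen=True)
class SphereFit:
    """One detected sphere: center (z, y, x) in µm, radius in µm, score."""

    center_um: tuple[float, float, float]
    radius_um: float
    score: float


@dataclass
class HoughParams:
    """Detection parameters.

    R_min/R_max (µm) bound the radius sweep and are dataset-specific (chosen
    from the manufacturer's size range in practice); radius_step defaults to
    one working-grid voxel.  edge_threshold is the gradient-magnitude
    fraction defining edge voxels; accumulator_threshold is the normalized
    support a peak must reach — the normalization makes a complete sphere
    score O(1) (typically ~2, since the thresholded edge band is a few
    voxels thick), while ghost peaks stay well below 0.5.
    min_center_separation (µm, default R_min) suppresses duplicate
    detections of one bead.  downsample_factor sets the working grid for
    voting (refinement always uses the full grid).
    """

    R_min: float
    R_max: float
    radius_step: float | None = None
    edge_threshold: float = 0.3
    accumulator_threshold: float = 0.5
    min_center_separation: float | None = None
    downsample_factor: int = 2
    smoothing_sigma: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.R_min < self.R_max):
            raise ValueError("need 0 < R_min < R_max")
        if self.radius_step is not None and not self.radius_step > 0:
            raise ValueError("radius_step must be > 0")


def sphere_metrics(R_i: float) -> tuple[float, float]:
    """Surface area 4πR² (µm²) and volume (4/3)πR³ (µm³) of a sphere."""
    if not R_i > 0:
        raise ValueError("radius must be positive")
    return 4.0 * np.pi * R_i**2, (4.0 / 3.0) * np.pi * R_i**3


def _edge_voxels(data: np.ndarray, sigma: float, threshold_frac: float):
    """Edge voxel coordinates, unit gradient directions and magnitudes."""
    smooth = ndimage.gaussian_filter(data.astype(np.float32), sigma)
    grads = np.gradient(smooth)
    mag = np.sqrt(sum(g * g for g in grads))
    peak = float(mag.max())
    if peak <= 0:
        return np.zeros((0, 3)), np.zeros((0, 3)), np.zeros(0)
    sel = mag > threshold_frac * peak
    coords = np.argwhere(sel).astype(np.float64)
    g = np.stack([grads[k][sel] for k in range(3)], axis=1).astype(np.float64)
    norms = np.linalg.norm(g, axis=1)
    g /= norms[:, None]
    return coords, g, norms


def _vote(coords, dirs, r, shape):
    acc = np.zeros(shape, dtype=np.float32)
    for sign in (1.0, -1.0):
        pts = np.round(coords + sign * r * dirs).astype(np.int64)
        ok = np.all((pts >= 0) & (pts < np.array(shape)), axis=1)
        pts = pts[ok]
        np.add.at(acc, (pts[:, 0], pts[:, 1], pts[:, 2]), 1.0)
    return acc


def _sphere_lsq(points: np.ndarray, weights: np.ndarray | None = None):
    """(Weighted) algebraic least-squares sphere fit to points."""
    A = np.column_stack([2.0 * points, np.ones(len(points))])
    b = (points**2).sum(axis=1)
    if weights is not None:
        sw = np.sqrt(weights)[:, None]
        A = A * sw
        b = b * sw[:, 0]
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    r = float(np.sqrt(max(sol[3] + (center**2).sum(), 0.0)))
    return center, r


def detect_spheres(volume: Volume3D, params: HoughParams) -> list[SphereFit]:
    """Detect spherical beads; fits sorted by descending accumulator score.

    Returns an empty list when no edges exist (e.g. all-background input).
    Deterministic for a fixed input.
    """
    vs = volume.voxel_size
    if params.R_max >= 0.5 * min(volume.shape) * vs:
        raise ValueError("R_max must be smaller than half the smallest grid extent")
    work = downsample(volume, params.downsample_factor)
    wvs = work.voxel_size

    coords, dirs, _ = _edge_voxels(work.data, params.smoothing_sigma, params.edge_threshold)
    if len(coords) == 0:
        return []

    step = (params.radius_step or wvs) / wvs  # working-grid voxels
    radii = np.arange(params.R_min / wvs, params.R_max / wvs + 1e-9, step)
    best_score = np.zeros(work.shape, dtype=np.float32)
    best_radius = np.zeros(work.shape, dtype=np.float32)
    # a delta of mass M smoothed by an isotropic Gaussian peaks at
    # M (2π)^{-3/2} σ^{-3}; normalizing by the theoretical shell support
    # 4πr² makes a perfect sphere score ~O(1) at every radius
    gauss_peak = (2.0 * np.pi) ** 1.5 * params.smoothing_sigma**3
    for r in radii:
        acc = _vote(coords, dirs, r, work.shape)
        acc = ndimage.gaussian_filter(acc, params.smoothing_sigma)
        acc *= gauss_peak / (4.0 * np.pi * r**2)
        upd = acc > best_score
        best_score[upd] = acc[upd]
        best_radius[upd] = r

    # candidate peaks: local maxima above the support-fraction threshold
    localmax = best_score == ndimage.maximum_filter(best_score, size=3)
    cand = np.argwhere(localmax & (best_score >= params.accumulator_threshold))
    if len(cand) == 0:
        return []
    scores = best_score[tuple(cand.T)]
    order = np.argsort(scores)[::-1]
    cand, scores = cand[order], scores[order]

    sep = (params.min_center_separation or params.R_min) / wvs
    kept: list[int] = []
    for k in range(len(cand)):
        if all(np.linalg.norm(cand[k] - cand[j]) >= sep for j in kept):
            kept.append(k)

    # sub-voxel refinement on the full-resolution edge map; the gradient
    # magnitude peaks at the true surface, so magnitude-weighted fits are
    # unbiased even though the thresholded edge band is several voxels thick
    full_coords, full_dirs, full_mags = _edge_voxels(
        volume.data, params.smoothing_sigma * params.downsample_factor,
        params.edge_threshold,
    )
    rmin_v, rmax_v = params.R_min / vs, params.R_max / vs
    fits: list[SphereFit] = []
    for k in kept:
        c = cand[k] * params.downsample_factor + (params.downsample_factor - 1) / 2.0
        r = best_radius[tuple(cand[k])] * params.downsample_factor
        offs = full_coords - c
        d = np.linalg.norm(offs, axis=1)
        near = (d >= max(rmin_v - 2, 1.0)) & (d <= rmax_v + 2)
        # keep voxels whose gradient is close to radial: rejects most edge
        # voxels belonging to neighbouring beads or the container wall
        radial = np.abs((offs[near] * full_dirs[near]).sum(axis=1) / d[near])
        idx = np.flatnonzero(near)[radial > 0.8]
        if len(idx) >= 10:
            pts, w = full_coords[idx], full_mags[idx]
            # weighted radius estimate over a window around the Hough radius
            # (weights divided by d² to cancel the r² shell-support growth)
            for window in (4.0, 3.0):
                dn = np.linalg.norm(pts - c, axis=1)
                band = np.abs(dn - r) <= window
                if band.sum() < 10:
                    break
                ws = w[band] / dn[band] ** 2
                r = float((ws * dn[band]).sum() / ws.sum())
                c, r = _sphere_lsq(pts[band], ws)
            # the gradient-magnitude peak of a Gaussian-smoothed convex
            # boundary sits ~sigma^2/R inside the true surface; undo it
            sigma_full = params.smoothing_sigma * params.downsample_factor
            r += sigma_full**2 / r
        fits.append(
            SphereFit(
                center_um=tuple(float(x) * vs for x in c),
                radius_um=float(r) * vs,
                score=float(scores[k]),
            )
        )
    fits.sort(key=lambda f: -f.score)
    return fits


def build_shell_mask(
    fits: list[SphereFit],
    volume: Volume3D,
    thickness: float = 10.0,
) -> np.ndarray:
    """Binary spherical shells at the detected centers/radii, for visual QC.

    A voxel is foreground when its center distance d (µm) to some fit center
    satisfies R − thickness/2 ≤ d ≤ R + thickness/2.  Overlaying the shells
    on the grayscale data shows how well the detections wrap the beads.
    """
    vs = volume.voxel_size
    out = np.zeros(volume.shape, dtype=bool)
    half = thickness / 2.0
    for fit in fits:
        c = np.array(fit.center_um) / vs
        r_out = (fit.radius_um + half) / vs
        lo = np.maximum(np.floor(c - r_out - 1).astype(int), 0)
        hi = np.minimum(np.ceil(c + r_out + 2).astype(int), volume.shape)
        grids = np.meshgrid(*[np.arange(lo[k], hi[k]) for k in range(3)], indexing="ij")
        d = np.sqrt(sum((g - c[k]) ** 2 for k, g in enumerate(grids))) * vs
        sub = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
        out[sub] |= (d >= fit.radius_um - half) & (d <= fit.radius_um + half)
    return out
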