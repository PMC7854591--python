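"""Small shared geometry helpers on voxel grids."""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

__all__ = ["hull_image", "ball_ops"]


def hull_image(mask: np.ndarray, return_hull: bool = False):
    """Discrete convex hull image of a boolean voxel mask.

    A voxel belongs to the hull image iff its center lies inside (or on, with
    a 1e-7 tolerance) the convex hull polytope of the foreground voxel
    centers.  Degenerate (flat) masks fall back to the mask itself.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no convex hull")
    # the hull is determined by boundary voxels only
    eroded = ndimage.binary_erosion(mask)
    surface = mask & ~eroded
    pts = np.argwhere(surface if surface.any() else mask).astype(np.float64)
    try:
        hull = ConvexHull(pts)
    except QhullError:
        # coplanar / collinear set: hull image degenerates to the mask
        return (mask.copy(), None) if return_hull else mask.copy()
    lo = pts.min(axis=0).astype(int)
    hi = pts.max(axis=0).astype(int)
    grids = np.meshgrid(
        *[np.arange(lo[k], hi[k] + 1) for k in range(3)], indexing="ij"
    )
    cand = np.stack([g.ravel() for g in grids], axis=1).astype(np.float64)
    # inside iff all halfspace constraints A x + b <= tol
    inside = np.ones(len(cand), dtype=bool)
    eqs = hull.equations
    for start in range(0, eqs.shape[0], 64):  # chunk to bound memory
        chunk = eqs[start : start + 64]
        inside &= (cand @ chunk[:, :3].T + chunk[:, 3]).max(axis=1) <= 1e-7
        if not inside.any():
            break
    out = np.zeros_like(mask)
    idx = cand[inside].astype(int)
    out[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    out |= mask  # guard: every foreground voxel is in its own hull image
    return (out, hull) if return_hull else out


class ball_ops:
    """Binary morphology with discrete spherical elements via distance maps.

    The element is the discrete ball {voxels with center distance <= r};
    implementing erosion/dilation through Euclidean distance transforms is
    exactly equivalent to the structuring-element definition but much faster
    for large radii.
    """

    @staticmethod
    def dilate(mask: np.ndarray, r: float) -> np.ndarray:
        if r <= 0:
            return mask.copy()
        dt = ndimage.distance_transform_edt(~mask)
        return dt <= r

    @staticmethod
    def erode(mask: np.ndarray, r: float) -> np.ndarray:
        if r <= 0:
            return mask.copy()
        dt = ndimage.distance_transform_edt(mask)
        return dt > r

    @classmethod
    def open(cls, mask: np.ndarray, r: float) -> np.ndarray:
        return cls.dilate(cls.erode(mask, r), r)

    @classmethod
    def close(cls, mask: np.ndarray, r: float) -> np.ndarray:
        # pad so closing near the border behaves as in an unbounded grid
        pad = int(np.ceil(r)) + 1
        padded = np.pad(mask, pad)
        out = cls.erode(cls.dilate(padded, r), r)
        return out[pad:-pad, pad:-pad, pad:-pad]
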