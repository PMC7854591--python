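"""Multilevel Otsu thresholding with staining-aware foreground selection.

Contrast-enhanced CT of hydrated beads produces three-peak histograms: two
background peaks (air and staining solution) and one bead peak.  Which class
is the bead depends on the staining regime: with positive staining the
contrast agent binds the bead matrix, so beads are the brightest class; with
negative staining the agent stains the surrounding liquid only, leaving the
beads as the middle class between dark air and bright liquid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import Volume3D

__all__ = ["OtsuResult", "multi_otsu", "select_foreground"]


@dataclass(frozen=True)
class OtsuResult:
    """Two thresholds splitting a histogram into three classes.

    ``thresholds = (t_low, t_high)`` with t_low < t_high, expressed on the
    gray scale of the input; ``class_fractions`` are the voxel fractions of
    the three classes (gray <= t_low, t_low < gray <= t_high, gray > t_high).
    """

    thresholds: tuple[float, float]
    class_fractions: tuple[float, float, float]


def _exhaustive_two_threshold_otsu(counts: np.ndarray) -> tuple[int, int]:
    """Exact maximizer of between-class variance over all threshold pairs.

    ``counts`` is a histogram over consecutive integer bins.  Returns bin
    indices (i, j), i < j, defining classes [0..i], (i..j], (j..end].
    Fully vectorized over the (i, j) grid, exact for <= 256 bins.
    """
    counts = np.asarray(counts, dtype=np.float64)
    n = counts.sum()
    levels = np.arange(counts.size, dtype=np.float64)
    w = np.concatenate([[0.0], np.cumsum(counts)])        # w[k] = sum counts[:k]
    m = np.concatenate([[0.0], np.cumsum(counts * levels)])

    i = np.arange(counts.size)
    # class sums for all (i, j): w0 = w[i+1], w1 = w[j+1]-w[i+1], w2 = n-w[j+1]
    w_hi = w[1:]  # w_hi[k] = sum counts[:k+1]
    m_hi = m[1:]
    w0 = w_hi[:, None]
    m0 = m_hi[:, None]
    w1 = w_hi[None, :] - w0
    m1 = m_hi[None, :] - m0
    w2 = n - w_hi[None, :]
    m2 = m_hi[-1] - m_hi[None, :]

    with np.errstate(divide="ignore", invalid="ignore"):
        var_between = (
            np.where(w0 > 0, m0**2 / w0, 0.0)
            + np.where(w1 > 0, m1**2 / w1, 0.0)
            + np.where(w2 > 0, m2**2 / w2, 0.0)
        )
    ii, jj = np.meshgrid(i, i, indexing="ij")
    var_between[ii >= jj] = -np.inf
    # require three nonempty classes so thresholds always separate something
    var_between[(w0 == 0) | (w1 == 0) | (np.broadcast_to(w2, var_between.shape) == 0)] = -np.inf
    best = np.unravel_index(np.argmax(var_between), var_between.shape)
    return int(best[0]), int(best[1])


def multi_otsu(volume: Volume3D | np.ndarray, n_classes: int = 3) -> OtsuResult:
    """Three-class Otsu thresholds of a grayscale volume.

    Uses native integer bins for 8-bit data and 256 equal-width bins
    otherwise; the threshold pair maximizing between-class variance is found
    by exhaustive search, so the optimum is exact on the discrete histogram.

    Raises
    ------
    ValueError
        If the volume holds fewer distinct gray values than classes
        (degenerate histogram), or n_classes != 3.
    """
    if n_classes != 3:
        raise ValueError("only the three-class (two-threshold) case is supported")
    data = volume.data if isinstance(volume, Volume3D) else np.asarray(volume)
    flat = data.ravel()
    if np.unique(flat[: 100_000]).size < n_classes and np.unique(flat).size < n_classes:
        raise ValueError("degenerate histogram: fewer distinct gray values than classes")

    if data.dtype == np.uint8:
        counts = np.bincount(flat, minlength=256)
        bin_values = np.arange(counts.size, dtype=np.float64)
    else:
        lo, hi = float(flat.min()), float(flat.max())
        counts, edges = np.histogram(flat, bins=256, range=(lo, hi))
        bin_values = 0.5 * (edges[:-1] + edges[1:])

    i, j = _exhaustive_two_threshold_otsu(counts)
    t_low, t_high = float(bin_values[i]), float(bin_values[j])

    n = flat.size
    f0 = float(np.count_nonzero(flat <= t_low)) / n
    f2 = float(np.count_nonzero(flat > t_high)) / n
    f1 = 1.0 - f0 - f2
    return OtsuResult(thresholds=(t_low, t_high), class_fractions=(f0, f1, f2))


def select_foreground(
    volume: Volume3D | np.ndarray, otsu: OtsuResult, staining: str
) -> np.ndarray:
    """Pick the bead class given the staining regime.

    positive staining: foreground = gray > t_high (brightest class);
    negative staining: foreground = t_low < gray <= t_high (middle class).
    Returns a boolean mask on the volume's grid; an empty mask is valid.
    """
    data = volume.data if isinstance(volume, Volume3D) else np.asarray(volume)
    t_low, t_high = otsu.thresholds
    if staining == "positive":
        return data > t_high
    if staining == "negative":
        return (data > t_low) & (data <= t_high)
    raise ValueError(f"unknown staining mode {staining!r}; use 'positive' or 'negative'")
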