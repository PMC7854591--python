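"""Cohort-level statistics for bead morphometrics.

Boxplot summaries use the midpoint quantile convention (linear interpolation
of the order statistics at probabilities (k − 0.5)/n) and the 1.5·IQR
outlier rule; swelling is quantified as the percent change of a central
measure of a morphometric between the dry and wet cohorts; attachment
surface area per dry weight links the imaged morphometrics to the mass-based
quantity manufacturers specify.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "BoxplotSummary",
    "DryWeightSpec",
    "quantile",
    "boxplot_summary",
    "swelling_change",
    "surface_per_dry_weight",
    "compare_groups_ttest",
    "ks_normality",
]


def quantile(values, p: float) -> float:
    """Quantile by linear interpolation at probabilities (k − 0.5)/n.

    Below the first and above the last midpoint the extreme order statistics
    are returned.
    """
    x = np.sort(np.asarray(values, dtype=np.float64))
    n = x.size
    if n == 0:
        raise ValueError("empty input")
    pos = p * n - 0.5  # 0-based index into the order statistics
    if pos <= 0:
        return float(x[0])
    if pos >= n - 1:
        return float(x[-1])
    lo = int(np.floor(pos))
    frac = pos - lo
    return float(x[lo] * (1 - frac) + x[lo + 1] * frac)


@dataclass
class BoxplotSummary:
    """Five-number summary with mean/std, whiskers and 1.5·IQR outliers."""

    n: int
    mean: float
    std: float
    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray


def boxplot_summary(values) -> BoxplotSummary:
    """Summarize one morphometric the way the cohort boxplots are drawn.

    Outliers are values above q3 + 1.5·(q3 − q1) or below q1 − 1.5·(q3 − q1);
    the whiskers are the extreme non-outlier values.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty input")
    q1 = quantile(x, 0.25)
    q3 = quantile(x, 0.75)
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    out = (x > hi_fence) | (x < lo_fence)
    inliers = x[~out]
    return BoxplotSummary(
        n=int(x.size),
        mean=float(x.mean()),
        std=float(x.std(ddof=1)) if x.size > 1 else 0.0,
        q1=q1,
        median=quantile(x, 0.5),
        q3=q3,
        whisker_low=float(inliers.min()),
        whisker_high=float(inliers.max()),
        outliers=np.sort(x[out]),
    )


def swelling_change(
    dry: BoxplotSummary, wet: BoxplotSummary, central: str = "median"
) -> float:
    """Percent change of a central measure from the dry to the wet cohort."""
    if central not in ("median", "mean"):
        raise ValueError("central must be 'median' or 'mean'")
    d = getattr(dry, central)
    w = getattr(wet, central)
    if d == 0:
        raise ValueError("dry central value is zero")
    return 100.0 * (w - d) / d


@dataclass
class DryWeightSpec:
    """Inputs for the surface-area-per-dry-weight estimate.

    mode 'nonswelling' uses the bead density d (g/ml); 'swelling_countpergram'
    uses the manufacturer's bead count per gram dry weight;
    'swelling_imagedcount' estimates that count as imaged_count /
    sample_weight (g) from the dry-state scan.
    """

    mode: str
    density: float | None = None  # g/ml
    count_per_gram: float | None = None  # 1/g
    sample_weight: float | None = None  # g
    imaged_count: int | None = None


_UM2_TO_CM2 = 1e-8
_UM3_TO_CM3 = 1e-12


def surface_per_dry_weight(records, spec: DryWeightSpec) -> float:
    """Attachment surface area per gram dry weight, cm²/g.

    Non-swelling beads: median surface / (median volume × density).  Swelling
    beads: median surface × beads-per-gram (either from the manufacturer or
    estimated from the imaged dry-sample count and the sample weight).
    Surface/volume medians are taken over the per-bead records; spherical
    records use 4πR² / (4/3)πR³, otherwise the convex surface area and bead
    volume.
    """
    records = list(records)
    if not records:
        raise ValueError("no bead records")
    surfaces = np.array([_surface_of(r) for r in records])
    volumes = np.array([_volume_of(r) for r in records])
    s_med = quantile(surfaces, 0.5)
    if spec.mode == "nonswelling":
        if spec.density is None:
            raise ValueError("nonswelling mode needs density")
        v_med = quantile(volumes, 0.5)
        return (s_med * _UM2_TO_CM2) / (v_med * _UM3_TO_CM3 * spec.density)
    if spec.mode == "swelling_countpergram":
        if spec.count_per_gram is None:
            raise ValueError("swelling_countpergram mode needs count_per_gram")
        return s_med * _UM2_TO_CM2 * spec.count_per_gram
    if spec.mode == "swelling_imagedcount":
        if not spec.imaged_count or not spec.sample_weight:
            raise ValueError(
                "swelling_imagedcount mode needs imaged_count > 0 and sample_weight"
            )
        return s_med * _UM2_TO_CM2 * (spec.imaged_count / spec.sample_weight)
    raise ValueError(f"unknown mode {spec.mode!r}")


def _surface_of(record) -> float:
    if hasattr(record, "radius_um"):
        return 4.0 * np.pi * record.radius_um**2
    return record.convex_surface_area


def _volume_of(record) -> float:
    if hasattr(record, "radius_um"):
        return (4.0 / 3.0) * np.pi * record.radius_um**3
    return record.bead_volume


def compare_groups_ttest(a, b, paired: bool = False, alpha: float = 0.05):
    """Two-sample Student's t-test (equal variances) on two cohorts.

    Returns (t, p, significant).  The unpaired equal-variance test is the
    default — validation cohorts generally have unequal sizes; a paired
    variant is available for matched samples.  Degenerate zero-variance
    inputs: p = 1 when the means agree, p = 0 otherwise.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if min(a.size, b.size) < 2:
        raise ValueError("need at least two observations per group")
    if paired:
        t, p = sps.ttest_rel(a, b)
    else:
        t, p = sps.ttest_ind(a, b, equal_var=True)
    if np.isnan(p):  # zero pooled variance
        same = np.isclose(a.mean(), b.mean())
        t, p = 0.0 if same else np.inf, 1.0 if same else 0.0
    return float(t), float(p), bool(p < alpha)


def ks_normality(values, alpha: float = 0.05):
    """One-sample Kolmogorov–Smirnov test of normality on z-scored data.

    The sample is standardized by its own mean and standard deviation and
    compared against the standard normal distribution (testing raw
    morphometrics against N(0, 1) directly would reject trivially on any
    scale).  Returns (D, p, reject) with rejection at the given level.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size < 5:
        raise ValueError("need at least 5 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    z = (x - x.mean()) / sd
    d, p = sps.kstest(z, "norm")
    return float(d), float(p), bool(p < alpha)
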