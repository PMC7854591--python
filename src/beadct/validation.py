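"""Scoring of a segmentation against a reference labeling.

Mirrors the manual-versus-automatic validation protocol: per-bead
morphometrics are computed for every label in both volumes, the two cohorts
are compared metric-by-metric as pooled distributions (mean, std, quartiles,
Student's t-test), and the bead-count discrepancy is reported as a percent
error.  A truth-matching score (one-to-one IoU matching) is also provided
for phantom studies where voxel-exact ground truth exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .morphometrics import BeadRecord, analyze_labels
from .segment import LabelVolume
from .stats import compare_groups_ttest, quantile

__all__ = [
    "MetricComparison",
    "ValidationReport",
    "count_error_percent",
    "validate_segmentation",
    "match_labels_iou",
]

_METRICS = [
    ("equivalent_diameter", "Equivalent Diameter [um]"),
    ("principal_axis_1", "Principal Axis 1 Length [um]"),
    ("principal_axis_2", "Principal Axis 2 Length [um]"),
    ("principal_axis_3", "Principal Axis 3 Length [um]"),
    ("convex_surface_area", "Convex surface area [um2]"),
    ("bead_volume", "Bead volume [um3]"),
    ("convex_hull_volume", "Convex hull volume [um3]"),
    ("open_pore_volume", "Open pore volume [um3]"),
    ("closed_pore_volume", "Closed pore volume [um3]"),
    ("porosity", "Porosity [/]"),
]


@dataclass
class MetricComparison:
    """One morphometric compared between the two cohorts."""

    metric: str
    reference: dict
    test: dict
    t: float
    p: float
    significant: bool


@dataclass
class ValidationReport:
    n_reference: int
    n_test: int
    percent_count_error: float
    rows: list[MetricComparison] = field(default_factory=list)

    @property
    def headline_count_error(self) -> int:
        """Count error rounded to the nearest integer percent."""
        return int(round(self.percent_count_error))

    def to_dict(self) -> dict:
        return {
            "n_reference": self.n_reference,
            "n_test": self.n_test,
            "percent_count_error": self.percent_count_error,
            "headline_count_error": self.headline_count_error,
            "metrics": {
                row.metric: {
                    "reference": row.reference,
                    "test": row.test,
                    "t": row.t,
                    "p": row.p,
                    "significant": row.significant,
                }
                for row in self.rows
            },
        }


def count_error_percent(n_reference: int, n_test: int) -> float:
    """Percent under-/over-estimation of the bead count, 100·(ref − test)/ref."""
    if n_reference <= 0:
        raise ValueError("reference count must be positive")
    return 100.0 * (n_reference - n_test) / n_reference


def _values(records: list[BeadRecord], key: str) -> np.ndarray:
    if key.startswith("principal_axis_"):
        idx = int(key[-1]) - 1
        return np.array([r.principal_axis_lengths[idx] for r in records])
    return np.array([getattr(r, key) for r in records])


def _summary(x: np.ndarray) -> dict:
    return {
        "mean": float(x.mean()),
        "std": float(x.std(ddof=1)) if x.size > 1 else 0.0,
        "q25": quantile(x, 0.25),
        "median": quantile(x, 0.5),
        "q75": quantile(x, 0.75),
    }


def validate_segmentation(
    reference: LabelVolume,
    test: LabelVolume,
    reference_mask: np.ndarray | None = None,
    test_mask: np.ndarray | None = None,
    probe_radii_vox=(np.inf,),
    alpha: float = 0.05,
) -> ValidationReport:
    """Compare two labelings of the same grid, cohort-style.

    Bead images are ``mask ∧ label`` when a binarized foreground mask is
    given (so pores are retained), otherwise the labels themselves.  Records
    are pooled per group — no bead-to-bead matching — and each morphometric
    row carries both groups' summary statistics and an unpaired t-test.
    """
    if reference.labels.shape != test.labels.shape:
        raise ValueError("reference and test labelings must share one grid")
    ref_mask = reference_mask if reference_mask is not None else reference.labels > 0
    tst_mask = test_mask if test_mask is not None else test.labels > 0
    ref_rec = analyze_labels(ref_mask, reference, probe_radii_vox=probe_radii_vox)
    tst_rec = analyze_labels(tst_mask, test, probe_radii_vox=probe_radii_vox)
    report = ValidationReport(
        n_reference=len(ref_rec),
        n_test=len(tst_rec),
        percent_count_error=count_error_percent(len(ref_rec), len(tst_rec)),
    )
    for key, label in _METRICS:
        a = _values(ref_rec, key)
        b = _values(tst_rec, key)
        if np.array_equal(a, b):
            t, p, sig = 0.0, 1.0, False  # identical cohorts
        else:
            t, p, sig = compare_groups_ttest(a, b, alpha=alpha)
        report.rows.append(
            MetricComparison(
                metric=label,
                reference=_summary(a),
                test=_summary(b),
                t=t,
                p=p,
                significant=sig,
            )
        )
    return report


def match_labels_iou(
    truth_labels: np.ndarray, test_labels: np.ndarray, iou_threshold: float = 0.5
) -> dict[int, int]:
    """Greedy one-to-one matching of truth to test labels by IoU.

    Returns {truth_id: test_id} for pairs with intersection-over-union at or
    above the threshold; each test label is used at most once.
    """
    truth_labels = np.asarray(truth_labels)
    test_labels = np.asarray(test_labels)
    both = (truth_labels > 0) & (test_labels > 0)
    pairs, counts = np.unique(
        np.stack([truth_labels[both], test_labels[both]]), axis=1, return_counts=True
    )
    t_sizes = np.bincount(truth_labels.ravel())
    s_sizes = np.bincount(test_labels.ravel())
    ious = counts / (
        t_sizes[pairs[0]] + s_sizes[pairs[1]] - counts
    )
    order = np.argsort(ious)[::-1]
    matched: dict[int, int] = {}
    used_test: set[int] = set()
    for k in order:
        if ious[k] < iou_threshold:
            break
        ti, si = int(pairs[0, k]), int(pairs[1, k])
        if ti in matched or si in used_test:
            continue
        matched[ti] = si
        used_test.add(si)
    return matched
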