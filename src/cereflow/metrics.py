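"""Segmentation-agreement metrics and observer-comparison statistics.

Agreement between two binary segmentations is summarized by the Dice score
(volume overlap), the Hausdorff distance (worst-case surface mismatch) and
the average symmetric surface distance (ASSD).  The distance metrics
operate on boundary voxels — mask voxels with at least one face-adjacent
background neighbor — with voxel-center world coordinates, so they scale
with the voxel spacing and read as millimetres.

Observer comparisons use relative Bland-Altman statistics against a
designated reference observer, the two-way random-effects single-measure
absolute-agreement intraclass correlation ICC(2,1), and a Shapiro-Wilk
normality gate choosing between an unpaired t-test and a Mann-Whitney U.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .io import SegmentationMask

__all__ = [
    "AgreementReport",
    "PairedStats",
    "dice",
    "hausdorff",
    "assd",
    "boundary_voxels",
    "agreement_report",
    "bland_altman",
    "icc",
    "group_compare",
]

_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)


@dataclasses.dataclass
class AgreementReport:
    dice: float
    hausdorff_mm: float
    assd_mm: float


@dataclasses.dataclass
class PairedStats:
    relative_bias_pct: float
    loa_pct: float
    icc: float
    p_value: float
    test_name: str


def _as_bool(mask) -> np.ndarray:
    arr = mask.labels if isinstance(mask, SegmentationMask) else np.asarray(mask)
    return arr.astype(bool)


def _check_congruent(x, y) -> tuple[np.ndarray, np.ndarray]:
    xb, yb = _as_bool(x), _as_bool(y)
    if xb.shape != yb.shape:
        raise ValueError(f"mask grids differ: {xb.shape} vs {yb.shape}")
    return xb, yb


def dice(x, y) -> float:
    """Dice score 2|X∩Y| / (|X|+|Y|); 1.0 when both masks are empty."""
    xb, yb = _check_congruent(x, y)
    denom = xb.sum() + yb.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(xb, yb).sum() / denom)


def boundary_voxels(mask) -> np.ndarray:
    """Indices (n, 3) of mask voxels with >= 1 face-adjacent background
    neighbor (grid-edge voxels count as boundary)."""
    mb = _as_bool(mask)
    interior = ndimage.binary_erosion(mb, structure=_FACE_STRUCTURE, border_value=0)
    return np.argwhere(mb & ~interior)


def _surface_points_mm(mask, spacing, full_set: bool) -> np.ndarray:
    pts = np.argwhere(_as_bool(mask)) if full_set else boundary_voxels(mask)
    if pts.shape[0] == 0:
        raise ValueError("metric undefined for an empty mask")
    return pts * np.asarray(spacing, dtype=float)


def hausdorff(x, y, spacing=(1.0, 1.0, 1.0), *, full_set: bool = False) -> float:
    """Symmetric Hausdorff distance in mm between two masks' boundaries.

    ``full_set=True`` uses every mask voxel instead of the boundary set.
    """
    xb, yb = _check_congruent(x, y)
    px = _surface_points_mm(xb, spacing, full_set)
    py = _surface_points_mm(yb, spacing, full_set)
    dxy = cKDTree(py).query(px, workers=-1)[0].max()
    dyx = cKDTree(px).query(py, workers=-1)[0].max()
    return float(max(dxy, dyx))


def assd(x, y, spacing=(1.0, 1.0, 1.0)) -> float:
    """Average symmetric surface distance in mm: the two directed sums of
    nearest-boundary distances divided by the total boundary-voxel count."""
    xb, yb = _check_congruent(x, y)
    px = _surface_points_mm(xb, spacing, full_set=False)
    py = _surface_points_mm(yb, spacing, full_set=False)
    dxy = cKDTree(py).query(px, workers=-1)[0]
    dyx = cKDTree(px).query(py, workers=-1)[0]
    return float((dxy.sum() + dyx.sum()) / (len(px) + len(py)))


def agreement_report(x, y, spacing=(1.0, 1.0, 1.0)) -> AgreementReport:
    return AgreementReport(
        dice=dice(x, y),
        hausdorff_mm=hausdorff(x, y, spacing),
        assd_mm=assd(x, y, spacing),
    )


# ---------------------------------------------------------------------------
# statistics


def bland_altman(test, ref) -> tuple[float, float]:
    """Relative bias (%) and limits of agreement (1.96 * sample SD of the
    relative differences, %) of *test* against the reference observer."""
    test = np.asarray(test, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if test.shape != ref.shape:
        raise ValueError("test and ref must have equal lengths")
    if test.size < 2:
        raise ValueError("need at least 2 paired values")
    if np.any(ref == 0):
        raise ValueError("reference values must be nonzero")
    d = 100.0 * (test - ref) / ref
    return float(d.mean()), float(1.96 * d.std(ddof=1))


def icc(test, ref) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single
    measurement, computed from the two-column (subject x rater) table.

    With mean squares from the two-way ANOVA (n subjects, k = 2 raters):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    """
    test = np.asarray(test, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if test.shape != ref.shape:
        raise ValueError("test and ref must have equal lengths")
    n = test.size
    if n < 3:
        raise ValueError("need at least 3 paired values")
    table = np.column_stack([ref, test])
    k = 2
    grand = table.mean()
    if np.allclose(table, grand):
        warnings.warn("degenerate data (all values equal); ICC set to 1", stacklevel=2)
        return 1.0
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((table - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))


def group_compare(a, b, alpha: float = 0.05) -> tuple[float, str]:
    """Compare two independent groups with a normality-gated test.

    Shapiro-Wilk is run on each group; when both p-values exceed 0.05 an
    unpaired t-test is used, otherwise a Mann-Whitney U.  Returns the
    p-value and the name of the test that ran.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 values")
    normal = all(stats.shapiro(g).pvalue > 0.05 for g in (a, b))
    if normal:
        p = stats.ttest_ind(a, b).pvalue
        name = "t-test"
    else:
        p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        name = "mann-whitney-u"
    return float(p), name


def paired_stats(test, ref) -> PairedStats:
    """Full observer-agreement summary for one parameter."""
    bias, loa = bland_altman(test, ref)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = icc(test, ref)
    p, name = group_compare(test, ref)
    return PairedStats(
        relative_bias_pct=bias, loa_pct=loa, icc=r, p_value=p, test_name=name
    )
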