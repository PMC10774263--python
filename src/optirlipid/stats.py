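"""Colocalization and group-comparison statistics.

Group comparisons use the classical two-sided two-sample t-test (Student,
pooled variance; Welch available by flag) or the two-sided paired t-test on
differences. The significance threshold alpha = 0.05 travels with every
result but is never applied silently. Box summaries follow the common
convention: quartiles by linear interpolation (type 7), whiskers at the
min/max of non-outlier values, outliers beyond 1.5x the interquartile range.

Colocalization between an OPTIR channel and a fluorescence channel is the
sample Pearson correlation over ROI pixels, after nearest-neighbour
resampling of the finer grid onto the coarser one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .exceptions import GeometryError
from .formats import ChannelImage, LabelMask

ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class BoxSummary:
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


def box_summary(values) -> BoxSummary:
    """Box-plot summary with 1.5x IQR outliers and type-7 quartiles."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("box_summary needs at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo_bound, hi_bound = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inliers = v[(v >= lo_bound) & (v <= hi_bound)]
    outliers = v[(v < lo_bound) | (v > hi_bound)]
    return BoxSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inliers.min()),
        whisker_high=float(inliers.max()),
        outliers=tuple(float(o) for o in np.sort(outliers)),
    )


@dataclass
class GroupComparison:
    """Result of a two-group comparison with full test metadata."""

    group_labels: tuple[str, str]
    values: tuple[np.ndarray, np.ndarray]
    test_name: str
    statistic: float
    p_value: float
    alpha: float
    degrees_of_freedom: float
    boxes: tuple[BoxSummary, BoxSummary]
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def significant_at_alpha(self) -> bool:
        return self.p_value < self.alpha


def two_sample_test(
    x,
    y,
    paired: bool = False,
    welch: bool = False,
    alpha: float = ALPHA_DEFAULT,
    labels: tuple[str, str] = ("group_1", "group_2"),
) -> GroupComparison:
    """Two-sided t-test between two groups with box summaries attached.

    Unpaired default is the classical Student (pooled-variance) two-sample
    t-test; set ``welch`` for unequal variances. ``paired`` tests the mean of
    elementwise differences; identical paired samples (zero-variance
    differences with zero mean) are reported as t = 0, p = 1 rather than
    undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need n >= 2 per group")
    if paired:
        if x.size != y.size:
            raise ValueError("paired test requires equal-length groups")
        diff = x - y
        if np.allclose(diff.std(ddof=1), 0.0) and np.allclose(diff.mean(), 0.0):
            stat, p, df = 0.0, 1.0, float(x.size - 1)
        else:
            res = sps.ttest_rel(x, y)
            stat, p, df = float(res.statistic), float(res.pvalue), float(res.df)
        name = "two-sided paired sample t-test"
    else:
        res = sps.ttest_ind(x, y, equal_var=not welch)
        stat, p, df = float(res.statistic), float(res.pvalue), float(res.df)
        name = (
            "two-sided two-sample t-test (Welch)"
            if welch
            else "two-sided two-sample t-test (Student, pooled variance)"
        )
    return GroupComparison(
        group_labels=labels,
        values=(x, y),
        test_name=name,
        statistic=stat,
        p_value=p,
        alpha=alpha,
        degrees_of_freedom=df,
        boxes=(box_summary(x), box_summary(y)),
    )


def _resample_to_common_grid(
    a: ChannelImage, b: ChannelImage
) -> tuple[np.ndarray, np.ndarray, float]:
    """Nearest-neighbour resample of the finer-grid image onto the coarser."""
    if math.isclose(a.pixel_size_um, b.pixel_size_um) and a.shape == b.shape:
        return a.pixels, b.pixels, a.pixel_size_um
    fine, coarse, swapped = (
        (a, b, False) if a.pixel_size_um <= b.pixel_size_um else (b, a, True)
    )
    rows = (np.arange(coarse.shape[0]) + 0.5) * coarse.pixel_size_um
    cols = (np.arange(coarse.shape[1]) + 0.5) * coarse.pixel_size_um
    ri = np.clip((rows / fine.pixel_size_um - 0.5).round().astype(int), 0, fine.shape[0] - 1)
    ci = np.clip((cols / fine.pixel_size_um - 0.5).round().astype(int), 0, fine.shape[1] - 1)
    fine_on_coarse = fine.pixels[np.ix_(ri, ci)]
    if swapped:
        return coarse.pixels, fine_on_coarse, coarse.pixel_size_um
    return fine_on_coarse, coarse.pixels, coarse.pixel_size_um


def pearson_coloc(
    a: ChannelImage,
    b: ChannelImage,
    roi: LabelMask | None = None,
    label: int | None = None,
) -> float:
    """Sample Pearson correlation between two channels over an ROI.

    ``roi`` restricts to labelled pixels (all labels > 0, or one ``label``);
    without it the whole field of view is used. Invariant to positive-slope
    affine transforms of either channel. Zero variance in either channel
    makes the coefficient undefined: NaN is returned with a warning.
    """
    pa, pb, pixel = _resample_to_common_grid(a, b)
    if pa.shape != pb.shape:
        raise GeometryError("channels do not cover the same field of view")
    if roi is not None:
        if roi.labels.shape != pa.shape:
            raise GeometryError("ROI mask shape differs from the common grid")
        sel = roi.labels == label if label is not None else roi.labels > 0
        va, vb = pa[sel], pb[sel]
    else:
        va, vb = pa.ravel(), pb.ravel()
    if va.size < 2:
        raise ValueError("need >= 2 pixels for a correlation")
    if np.std(va) == 0 or np.std(vb) == 0:
        warnings.warn("zero variance in a channel: Pearson r undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(va, vb)[0, 1])
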