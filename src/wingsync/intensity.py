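"""Fluorescence-intensity measurements and comparisons.

Covers the circular-ROI mean-gray measurement (the ImageJ
"enlarge 4 px, measure" macro) applied to Z-disc spots, and the group
comparisons used for the resulting intensity tables: Welch's two-sample
t-test with Welch-Satterthwaite degrees of freedom, followed by a
Bonferroni correction over the requested pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RoiSpec",
    "WelchResult",
    "roi_mean_intensity",
    "welch_t_test",
    "bonferroni",
    "compare_groups",
]


@dataclass(frozen=True)
class RoiSpec:
    """A circular region of interest.

    ``center_xy`` is a 0-based pixel coordinate (x rightward, y downward);
    a pixel belongs to the ROI when its centre lies within ``radius_px``
    of the centre, boundary inclusive.
    """

    center_xy: tuple[float, float]
    radius_px: float = 4.0

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValueError("radius_px must be positive")


@dataclass(frozen=True)
class WelchResult:
    """Welch two-sample t-test result, optionally multiplicity-adjusted."""

    t: float
    df: float
    p_value: float
    p_adjusted: float | None = None


def roi_mean_intensity(image: np.ndarray, roi: RoiSpec) -> float:
    """Mean gray value inside a circular ROI.

    Pixels whose integer centres lie within ``roi.radius_px`` of
    ``roi.center_xy`` (inclusive) contribute; pixels outside the image are
    excluded from both numerator and denominator, so an ROI at a corner
    averages over the in-bounds part only.  Raises ``ValueError`` if no
    in-bounds pixel falls inside the ROI.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be a 2-D array")
    h, w = image.shape
    cx, cy = roi.center_xy
    r = roi.radius_px
    x_lo, x_hi = max(0, math.floor(cx - r)), min(w - 1, math.ceil(cx + r))
    y_lo, y_hi = max(0, math.floor(cy - r)), min(h - 1, math.ceil(cy + r))
    if x_lo > x_hi or y_lo > y_hi:
        raise ValueError("ROI lies entirely outside the image")
    ys, xs = np.mgrid[y_lo:y_hi + 1, x_lo:x_hi + 1]
    inside = (xs - cx) ** 2 + (ys - cy) ** 2 <= r * r + 1e-12
    if not inside.any():
        raise ValueError("ROI contains no in-bounds pixel centres")
    return float(image[y_lo:y_hi + 1, x_lo:x_hi + 1][inside].mean())


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Welch's unequal-variance two-sample t-test, two-sided.

    Degrees of freedom follow the Welch-Satterthwaite approximation.
    Both samples need at least two values and non-zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.var(x, ddof=1) == 0 or np.var(y, ddof=1) == 0:
        raise ValueError("degenerate sample: zero variance makes the t statistic unreliable")
    res = stats.ttest_ind(x, y, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df),
                       p_value=float(res.pvalue))


def bonferroni(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni adjustment: ``p_adj = min(1, m * p)``.

    ``m`` defaults to the number of p-values and may not be smaller.
    """
    p_values = list(p_values)
    if m is None:
        m = len(p_values)
    if m < len(p_values):
        raise ValueError(f"m={m} is smaller than the number of tests ({len(p_values)})")
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p!r} outside [0, 1]")
    return [min(1.0, m * p) for p in p_values]


def compare_groups(
    samples: Mapping[str, Sequence[float]],
    comparisons: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Welch-test each requested pair of groups, Bonferroni-adjusted.

    ``samples`` maps group labels to value sequences; ``comparisons``
    lists (label_a, label_b) pairs.  The Bonferroni multiplier is the
    number of requested pairs.  Returns a tidy DataFrame with one row per
    comparison: group_a, group_b, t, df, p_value, p_adjusted.
    """
    for pair in comparisons:
        for label in pair:
            if label not in samples:
                raise KeyError(f"unknown group label {label!r}")
    results = [welch_t_test(samples[a], samples[b]) for a, b in comparisons]
    adjusted = bonferroni([r.p_value for r in results], m=len(comparisons))
    return pd.DataFrame({
        "group_a": [a for a, _ in comparisons],
        "group_b": [b for _, b in comparisons],
        "t": [r.t for r in results],
        "df": [r.df for r in results],
        "p_value": [r.p_value for r in results],
        "p_adjusted": adjusted,
    })
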