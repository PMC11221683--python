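"""Count statistics: affected-myofibril ratios, exact binomial confidence
intervals, and the two-sample proportion test with continuity correction.

These are the statistics reported with the phenotype bar plots: per-image
ratios of affected myofibrils pooled over images, a 95% Clopper-Pearson
(exact binomial) interval for the pooled ratio, and Yates' continuity-
corrected chi-square test for equality of two proportions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .simulate import PHENOTYPE_CLASSES, PhenotypeCount

__all__ = [
    "ProportionResult",
    "TestResult",
    "affected_ratio",
    "pooled_affected_ratio",
    "clopper_pearson_ci",
    "two_proportion_test",
]


@dataclass(frozen=True)
class ProportionResult:
    """A binomial proportion estimate with its exact confidence interval."""

    k: int
    n: int
    p_hat: float
    ci_low: float
    ci_high: float
    conf_level: float = 0.95


@dataclass(frozen=True)
class TestResult:
    """A chi-square test result: statistic, degrees of freedom, p-value."""

    statistic: float
    df: int
    p_value: float
    method: str


def affected_ratio(count: PhenotypeCount, phenotype_class: str) -> float:
    """Ratio of affected myofibrils in one image: class count / total count."""
    if phenotype_class not in PHENOTYPE_CLASSES:
        raise ValueError(
            f"phenotype_class must be one of {PHENOTYPE_CLASSES}, got {phenotype_class!r}"
        )
    if count.n_total <= 0:
        raise ValueError(f"{count.image_id}: n_total must be positive")
    return getattr(count, f"n_{phenotype_class}") / count.n_total


def pooled_affected_ratio(
    counts: Iterable[PhenotypeCount], phenotype_class: str
) -> ProportionResult:
    """Pooled affected ratio over images: sum of class counts / sum of totals.

    Pooling sums counts across images so the denominator is the total
    number of myofibrils scored; the interval is the exact binomial CI on
    the pooled counts.
    """
    if phenotype_class not in PHENOTYPE_CLASSES:
        raise ValueError(
            f"phenotype_class must be one of {PHENOTYPE_CLASSES}, got {phenotype_class!r}"
        )
    counts = list(counts)
    if not counts:
        raise ValueError("no phenotype counts to pool")
    k = sum(getattr(c, f"n_{phenotype_class}") for c in counts)
    n = sum(c.n_total for c in counts)
    return clopper_pearson_ci(k, n)


def clopper_pearson_ci(k: int, n: int, conf_level: float = 0.95) -> ProportionResult:
    """Exact binomial (Clopper-Pearson) confidence interval for k successes in n trials.

    The bounds invert the binomial tail probabilities at level
    ``(1 - conf_level) / 2`` each; they are evaluated with the beta-quantile
    closed form.  The lower bound is 0 when ``k = 0`` and the upper bound
    is 1 when ``k = n``.
    """
    if not (isinstance(k, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise ValueError("k and n must be integers")
    if n < 1 or k < 0 or k > n:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if not 0.0 < conf_level < 1.0:
        raise ValueError(f"conf_level must lie in (0, 1), got {conf_level!r}")
    alpha = 1.0 - conf_level
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2.0, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return ProportionResult(k=int(k), n=int(n), p_hat=k / n,
                            ci_low=low, ci_high=high, conf_level=conf_level)


def two_proportion_test(
    k1: int, n1: int, k2: int, n2: int, continuity: bool = True
) -> TestResult:
    """Two-sample test for equality of proportions (chi-square, df = 1).

    With ``continuity`` the Yates correction is applied to the pooled 2x2
    table: each cell contributes ``(max(|O - E| - 0.5, 0))**2 / E``, the
    correction capped so it can never overshoot past zero.  Expected counts
    come from the table margins.  When the pooled proportion is 0 or 1 the
    statistic is defined as 0 with p = 1 (a warning is emitted), since no
    difference is estimable.
    """
    for name, value in (("n1", n1), ("n2", n2)):
        if value < 1:
            raise ValueError(f"{name} must be at least 1")
    for name, k, n in (("k1", k1, n1), ("k2", k2, n2)):
        if not 0 <= k <= n:
            raise ValueError(f"{name} must lie in [0, n], got {k}")

    method = ("2-sample test for equality of proportions"
              + (" with continuity correction" if continuity else ""))
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        warnings.warn("pooled proportion is degenerate (0 or 1); statistic set to 0",
                      stacklevel=2)
        return TestResult(statistic=0.0, df=1, p_value=1.0, method=method)

    observed = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    row = observed.sum(axis=1, keepdims=True)
    col = observed.sum(axis=0, keepdims=True)
    expected = row @ col / observed.sum()
    dev = np.abs(observed - expected)
    if continuity:
        dev = np.maximum(dev - 0.5, 0.0)
    statistic = float(np.sum(dev ** 2 / expected))
    p_value = float(stats.chi2.sf(statistic, df=1))
    return TestResult(statistic=statistic, df=1, p_value=p_value, method=method)
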