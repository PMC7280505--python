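"""Cross-method agreement statistics: Bland-Altman and identity regression.

These quantify whether different aEEG algorithms yield interchangeable
neurovascular-coupling estimates across subjects: pairwise differences of
significant-pixel counts with mean ± 1.96 SD limits of agreement, ordinary
least squares against the line of identity, and the relationship between
per-subject pixel counts and the cross-method coefficient of variation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = ["BlandAltmanResult", "RegressionResult", "bland_altman", "identity_regression", "cov_vs_pix"]


@dataclass(frozen=True)
class BlandAltmanResult:
    """Pairwise agreement summary with mean ± ``limit_multiplier``·SD limits."""

    diffs: np.ndarray
    means: np.ndarray
    mean_diff: float
    sd_diff: float
    upper_limit: float
    lower_limit: float
    n_outside: int
    limit_multiplier: float = 1.96


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit y = slope·x + intercept with Pearson r."""

    slope: float
    intercept: float
    r: float
    identity_distance: float  # Euclidean distance of (slope, intercept) from (1, 0)


def bland_altman(
    a: Sequence[float], b: Sequence[float], limit_multiplier: float = 1.96
) -> BlandAltmanResult:
    """Bland-Altman agreement between paired measurements a and b.

    diffs = a − b are plotted against means (a + b)/2; the limits of
    agreement are mean_diff ± limit_multiplier × sample SD (ddof=1).
    ``n_outside`` counts diffs strictly outside the limits.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-d sequences of equal length")
    if a.size < 2:
        raise ValueError("need at least two paired measurements")
    diffs = a - b
    means = (a + b) / 2.0
    mean_diff = float(np.mean(diffs))
    sd_diff = float(np.std(diffs, ddof=1))
    upper = mean_diff + limit_multiplier * sd_diff
    lower = mean_diff - limit_multiplier * sd_diff
    n_outside = int(np.sum((diffs < lower) | (diffs > upper)))
    return BlandAltmanResult(diffs, means, mean_diff, sd_diff, upper, lower, n_outside, limit_multiplier)


def identity_regression(a: Sequence[float], b: Sequence[float]) -> RegressionResult:
    """OLS of b on a, reported against the line of identity (slope 1, intercept 0)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need at least three paired values")
    if np.std(a) == 0:
        raise ValueError("zero variance in predictor; regression undefined")
    fit = stats.linregress(a, b)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        identity_distance=float(np.hypot(fit.slope - 1.0, fit.intercept)),
    )


def cov_vs_pix(
    pix_per_subject: Mapping[str, Sequence[float]],
    cov_per_subject: Sequence[float],
) -> dict[str, RegressionResult]:
    """Per-method OLS of the cross-method COV on that method's pixel counts.

    A negative slope means stronger coupling (more significant pixels) comes
    with less disagreement between aEEG algorithms.
    """
    cov = np.asarray(cov_per_subject, dtype=float)
    if cov.size < 3:
        raise ValueError("need at least three subjects")
    out: dict[str, RegressionResult] = {}
    for method, pix in pix_per_subject.items():
        p = np.asarray(pix, dtype=float)
        if p.shape != cov.shape:
            raise ValueError(f"method {method}: pixel counts and COVs differ in length")
        out[method] = identity_regression(p, cov)
    return out
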