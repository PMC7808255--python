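"""Correlation and simple regression as applied to the ΔΔ tables.

Implements the product-moment (Pearson) correlation, the adjusted R²

    R²_adj = 1 − (1 − R²)(n − 1)/(n − k − 1)

with k regressors (k = 1 throughout this pipeline), and the ordinary
least-squares line. Note: one published rendering of the Pearson formula
shows ``+ (Σy)²`` in the denominator; the mathematically correct minus
sign is used here — it is also the only reading consistent with the
published adjusted-R² values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "CorrelationReport",
    "pearson",
    "adjusted_r2",
    "ols_fit",
    "correlation_report",
]


@dataclass(frozen=True, slots=True)
class CorrelationReport:
    n: int
    pearson_r: float
    r_squared: float
    adjusted_r_squared: float
    slope: float
    intercept: float


def _validate_xy(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if xa.size < 3:
        raise ValueError("need at least 3 points")
    return xa, ya


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient.

    r = [nΣxy − ΣxΣy] / sqrt([nΣx² − (Σx)²][nΣy² − (Σy)²])
    """
    xa, ya = _validate_xy(x, y)
    n = xa.size
    sx, sy = xa.sum(), ya.sum()
    sxx, syy, sxy = (xa * xa).sum(), (ya * ya).sum(), (xa * ya).sum()
    dx = n * sxx - sx * sx
    dy = n * syy - sy * sy
    if dx <= 0 or dy <= 0:
        raise ValueError("zero variance in x or y")
    r = (n * sxy - sx * sy) / np.sqrt(dx * dy)
    return float(np.clip(r, -1.0, 1.0))


def adjusted_r2(r: float, n: int, k: int = 1) -> float:
    """Adjusted coefficient of determination for n points and k regressors.

    May legitimately be negative when r² is small relative to the degrees
    of freedom spent.
    """
    if n <= k + 1:
        raise ValueError("need n > k + 1")
    r2 = r * r
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - k - 1))


def ols_fit(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Ordinary least-squares line: returns (slope, intercept)."""
    xa, ya = _validate_xy(x, y)
    xm, ym = xa.mean(), ya.mean()
    sxx = ((xa - xm) ** 2).sum()
    if sxx == 0:
        raise ValueError("zero variance in x")
    slope = float(((xa - xm) * (ya - ym)).sum() / sxx)
    return slope, float(ym - slope * xm)


def correlation_report(
    x: Sequence[float], y: Sequence[float], k: int = 1
) -> CorrelationReport:
    """Pearson r, R², adjusted R² and the OLS line in one report."""
    xa, ya = _validate_xy(x, y)
    r = pearson(xa, ya)
    slope, intercept = ols_fit(xa, ya)
    return CorrelationReport(
        n=int(xa.size),
        pearson_r=r,
        r_squared=r * r,
        adjusted_r_squared=adjusted_r2(r, xa.size, k),
        slope=slope,
        intercept=intercept,
    )
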