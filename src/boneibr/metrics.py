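"""Comparison metrics for predicted load vectors.

Covers the off-axis angle from the 3-axis, angle and magnitude similarity
scores in [0, 1], and per-component regression statistics including Lin's
concordance correlation coefficient (population variances, reported in %).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "off_axis_angle",
    "angle_score",
    "magnitude_score",
    "regression_stats",
    "RegressionStats",
]


def off_axis_angle(force: np.ndarray) -> float:
    """Angle in degrees between a force vector and the +3 axis."""
    f = np.asarray(force, dtype=float)
    norm = np.linalg.norm(f)
    if norm == 0:
        raise ValueError("angle undefined for the zero vector")
    cos = np.clip(f[2] / norm, -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def angle_score(a: np.ndarray, b: np.ndarray) -> float:
    """1 - angle(a, b) / pi: 1 for parallel, 0.5 orthogonal, 0 antiparallel."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("angle score undefined for zero vectors")
    cos = np.clip(a @ b / (na * nb), -1.0, 1.0)
    return float(1.0 - np.arccos(cos) / np.pi)


def magnitude_score(a: np.ndarray, b: np.ndarray) -> float:
    """1 - sqrt((|a| - |b|)^2 / (|a|^2 + |b|^2)): 1 equal, 0 if one is zero."""
    na = np.linalg.norm(np.asarray(a, dtype=float))
    nb = np.linalg.norm(np.asarray(b, dtype=float))
    denom = na**2 + nb**2
    if denom == 0:
        raise ValueError("magnitude score undefined when both vectors are zero")
    return float(1.0 - np.sqrt((na - nb) ** 2 / denom))


@dataclass
class RegressionStats:
    slope: float
    intercept: float
    r_squared: float  # percent
    ccc: float  # percent


def regression_stats(x: np.ndarray, y: np.ndarray) -> RegressionStats:
    """OLS slope/intercept plus R^2 and Lin's CCC (both in percent).

    CCC = 2 cov(x, y) / (var(x) + var(y) + (mean x - mean y)^2) with
    population (n-denominator) variances, per Lin's original definition.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("regression undefined for constant x")
    mx, my = x.mean(), y.mean()
    sxx = np.mean((x - mx) ** 2)
    syy = np.mean((y - my) ** 2)
    sxy = np.mean((x - mx) * (y - my))
    slope = sxy / sxx
    intercept = my - slope * mx
    r2 = (sxy**2 / (sxx * syy)) if syy > 0 else 0.0
    ccc = 2 * sxy / (sxx + syy + (mx - my) ** 2)
    return RegressionStats(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(100 * r2),
        ccc=float(100 * ccc),
    )
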