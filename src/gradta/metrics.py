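"""Evaluation statistics for affinity regression: MSE, CI, rm² and Spearman.

The concordance index (CI) measures ranking agreement: over all ordered
pairs with distinct true affinities, a pair scores 1 when the predictions
are ordered the same way, 0.5 when the predictions tie, 0 otherwise.  rm²
is the QSAR external-validation statistic r² * (1 - sqrt(r² - r₀²)), where
r² is the squared Pearson correlation and r₀² the coefficient of
determination of a regression through the origin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class MetricsReport:
    mse: float
    ci: float
    rm2: float
    spearman: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def mse_metric(y, p) -> float:
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError("y and p must have equal length")
    if y.size == 0:
        raise ValueError("mse_metric requires at least one pair")
    return float(np.mean((p - y) ** 2))


def concordance_index(y, p) -> float:
    """CI = sum over pairs y_i > y_j of h(p_i - p_j), normalised by the
    number of such pairs; h is 1 / 0.5 / 0 for positive / zero / negative.

    Raises if all true values are equal (no comparable pairs).
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError("y and p must have equal length")
    # vectorised over the pair matrix; the O(n^2) memory is fine at
    # evaluation sizes used here
    dy = y[:, None] - y[None, :]
    dp = p[:, None] - p[None, :]
    mask = dy > 0
    z = int(mask.sum())
    if z == 0:
        raise ValueError("concordance index undefined: all true values equal")
    h = np.where(dp > 0, 1.0, np.where(dp == 0, 0.5, 0.0))
    return float(h[mask].sum() / z)


def _r0_squared(y, p) -> float:
    """Coefficient of determination of regressing y on p through the origin."""
    denom = float(np.sum(p * p))
    if denom == 0.0:
        return 0.0
    k = float(np.sum(y * p)) / denom
    ss_res = float(np.sum((y - k * p) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("rm2 undefined: zero variance in y")
    return 1.0 - ss_res / ss_tot


def rm2_metric(y, p, *, symmetric: bool = False) -> float:
    """rm² = r² * (1 - sqrt(r² - r₀²)).

    r² is the squared Pearson correlation (intercept fitted); r₀² comes from
    the through-origin regression of observed on predicted.  With
    ``symmetric=True`` the through-origin regression runs the other way
    (predicted on observed).  A numerically negative radicand is clamped to
    zero with a warning.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError("y and p must have equal length")
    if y.size < 3:
        raise ValueError("rm2 requires at least 3 pairs")
    if np.std(y) == 0 or np.std(p) == 0:
        raise ValueError("rm2 undefined: zero variance input")
    r = float(stats.pearsonr(y, p).statistic)
    r2 = r * r
    r02 = _r0_squared(p, y) if symmetric else _r0_squared(y, p)
    gap = r2 - r02
    if gap < 0:
        if gap < -1e-9:
            warnings.warn(
                f"rm2: r0^2 ({r02:.6f}) exceeds r^2 ({r2:.6f}); clamping",
                RuntimeWarning,
                stacklevel=2,
            )
        gap = 0.0
    return float(r2 * (1.0 - np.sqrt(gap)))


def spearman_metric(y, p) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError("y and p must have equal length")
    if y.size == 0:
        raise ValueError("spearman undefined on empty input")
    return float(stats.spearmanr(y, p).statistic)


def metrics_report(y, p) -> MetricsReport:
    """All four regression metrics in one report."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    return MetricsReport(
        mse=mse_metric(y, p),
        ci=concordance_index(y, p),
        rm2=rm2_metric(y, p),
        spearman=spearman_metric(y, p),
        n=int(y.size),
    )
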