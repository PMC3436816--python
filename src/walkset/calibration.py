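"""Regression-based calibration of the Xd significance threshold.

The Xd scores of reference sets with non-zero overlap correlate strongly
with their overlap q-values.  We fit ordinary least squares of Xd on
``x = -log10(q)`` and place the significance cutoff at the upper bound of
the confidence band for the mean response evaluated at the q-value cutoff
(default 0.05), so the threshold carries an increment for the uncertainty
of the fitted line.  A raw-q x-axis and a prediction band are available as
config alternatives.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.stats

log = logging.getLogger(__name__)

__all__ = [
    "RegressionFit",
    "fit_xd_q_regression",
    "significance_threshold",
    "plot_calibration",
]


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    residual_std: float
    n_points: int
    pearson_r: float
    x_transform: str = "neglog10"
    threshold: float | None = None
    valid: bool = True
    # internals needed for the confidence band
    x_mean: float = math.nan
    x_ss: float = math.nan  # sum of squared deviations of x


def _transform_q(q: np.ndarray, x_transform: str) -> np.ndarray:
    if x_transform == "neglog10":
        return -np.log10(q)
    if x_transform == "raw":
        return q.copy()
    raise ValueError(f"unknown x transform {x_transform!r}")


def fit_xd_q_regression(
    pairs: Sequence[tuple[float, float]], x_transform: str = "neglog10"
) -> RegressionFit:
    """OLS of Xd on the transformed q-value over (xd, q) pairs.

    Pairs with non-finite xd or q outside (0, 1] are dropped (zero-overlap
    sets, whose q is meaningless, must be excluded by the caller).  Fewer
    than 3 usable points, or degenerate variance in either variable, yields
    a fit flagged invalid (callers fall back to a configured threshold).
    """
    usable = [
        (xd, q)
        for xd, q in pairs
        if math.isfinite(xd) and math.isfinite(q) and 0.0 < q <= 1.0
    ]
    if len(usable) < 3:
        log.warning("calibration unavailable: only %d usable points", len(usable))
        return RegressionFit(
            slope=math.nan, intercept=math.nan, residual_std=math.nan,
            n_points=len(usable), pearson_r=math.nan,
            x_transform=x_transform, valid=False,
        )
    y = np.array([xd for xd, _ in usable])
    x = _transform_q(np.array([q for _, q in usable]), x_transform)
    n = len(usable)
    x_mean, y_mean = float(x.mean()), float(y.mean())
    sxx = float(np.sum((x - x_mean) ** 2))
    syy = float(np.sum((y - y_mean) ** 2))
    sxy = float(np.sum((x - x_mean) * (y - y_mean)))
    if sxx == 0.0 or syy == 0.0:
        log.warning("calibration degenerate: zero variance in x or xd")
        return RegressionFit(
            slope=0.0 if sxx > 0 else math.nan, intercept=y_mean,
            residual_std=math.nan, n_points=n, pearson_r=math.nan,
            x_transform=x_transform, valid=False, x_mean=x_mean, x_ss=sxx,
        )
    slope = sxy / sxx
    intercept = y_mean - slope * x_mean
    resid = y - (intercept + slope * x)
    sse = float(np.sum(resid**2))
    residual_std = math.sqrt(max(sse, 0.0) / (n - 2)) if n > 2 else math.nan
    pearson_r = sxy / math.sqrt(sxx * syy)
    return RegressionFit(
        slope=slope, intercept=intercept, residual_std=residual_std,
        n_points=n, pearson_r=pearson_r, x_transform=x_transform,
        valid=True, x_mean=x_mean, x_ss=sxx,
    )


def significance_threshold(
    fit: RegressionFit,
    q_cut: float = 0.05,
    conf: float = 0.95,
    band: str = "confidence",
    fallback: float | None = None,
) -> float:
    """Xd cutoff: upper bound of the regression band at the q-value cutoff.

    ``band="confidence"`` (default) uses the mean-response confidence band;
    ``band="prediction"`` the wider prediction band.  An invalid fit returns
    ``fallback`` (or raises if no fallback is configured).
    """
    if not (0.0 < q_cut <= 1.0):
        raise ValueError("q_cut must lie in (0, 1]")
    if band not in ("confidence", "prediction"):
        raise ValueError(f"unknown band type {band!r}")
    if not fit.valid:
        if fallback is None:
            raise ValueError("calibration unavailable and no fallback threshold set")
        log.warning("using fallback Xd threshold %.4g", fallback)
        return fallback
    x0 = float(_transform_q(np.array([q_cut]), fit.x_transform)[0])
    mean_resp = fit.intercept + fit.slope * x0
    n = fit.n_points
    tval = float(scipy.stats.t.ppf(0.5 + conf / 2.0, n - 2))
    leverage = 1.0 / n + (x0 - fit.x_mean) ** 2 / fit.x_ss
    if band == "prediction":
        leverage += 1.0
    halfwidth = tval * fit.residual_std * math.sqrt(leverage)
    return float(mean_resp + halfwidth)


def plot_calibration(
    fit: RegressionFit,
    pairs: Sequence[tuple[float, float]],
    threshold: float,
    path: str | Path,
    q_cut: float = 0.05,
) -> None:
    """Scatter of the fitted points with the regression line and threshold."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    usable = [(xd, q) for xd, q in pairs
              if math.isfinite(xd) and math.isfinite(q) and 0.0 < q <= 1.0]
    fig, ax = plt.subplots(figsize=(6, 4.5))
    if usable:
        y = np.array([xd for xd, _ in usable])
        x = _transform_q(np.array([q for _, q in usable]), fit.x_transform)
        ax.scatter(x, y, s=18, alpha=0.7, label="reference sets")
        if fit.valid:
            xs = np.linspace(min(x.min(), 0), max(x.max(), 1.5), 100)
            ax.plot(xs, fit.intercept + fit.slope * xs, "r-", lw=1,
                    label=f"fit (r={fit.pearson_r:.2f})")
    ax.axhline(threshold, color="k", ls="--", lw=1,
               label=f"Xd threshold {threshold:.3f}")
    xlabel = "-log10(q)" if fit.x_transform == "neglog10" else "q"
    ax.set_xlabel(f"overlap significance, {xlabel}")
    ax.set_ylabel("Xd score")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
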