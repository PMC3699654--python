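"""Population-level summaries and comparisons.

Maximum-rescaled kernel density estimates for comparing distribution
shapes, bootstrap standard errors for medians, two-sided Mann-Whitney U
tests for group comparisons, Deming (total least squares) regression for
between-instrument comparisons, and logistic growth-curve fits for
culture OD series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DegenerateInputError

__all__ = [
    "RescaledDensityCurve",
    "GrowthFit",
    "DemingFit",
    "rescaled_kde",
    "median_summary",
    "mann_whitney_u",
    "deming_fit",
    "logistic_growth_fit",
    "batch_summary",
]


@dataclass(frozen=True)
class RescaledDensityCurve:
    """A Gaussian KDE rescaled so that its maximum equals one."""

    grid: np.ndarray
    height: np.ndarray  # max == 1
    bandwidth: float  # same units as grid
    bandwidth_rule: str


def rescaled_kde(
    values,
    bandwidth_rule: str = "scott",
    n_grid: int = 1024,
) -> RescaledDensityCurve:
    """Gaussian kernel density estimate divided by its maximum.

    The grid spans the data range padded by four bandwidths, so the
    un-rescaled curve integrates to ~1.  ``bandwidth_rule`` is "scott",
    "silverman", or a positive float (passed to scipy's ``bw_method``).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        raise DegenerateInputError("KDE needs >= 2 distinct values")
    bw_method = bandwidth_rule if isinstance(bandwidth_rule, str) else float(bandwidth_rule)
    kde = stats.gaussian_kde(x, bw_method=bw_method)
    bandwidth = float(np.sqrt(kde.covariance[0, 0]))
    grid = np.linspace(x.min() - 4 * bandwidth, x.max() + 4 * bandwidth, n_grid)
    height = kde(grid)
    return RescaledDensityCurve(
        grid=grid,
        height=height / height.max(),
        bandwidth=bandwidth,
        bandwidth_rule=str(bandwidth_rule),
    )


def median_summary(values, n_boot: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Sample median and its seeded bootstrap standard error."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise DegenerateInputError("median_summary requires a non-empty sample")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    boot_medians = np.median(x[idx], axis=1)
    return float(np.median(x)), float(np.std(boot_medians, ddof=1))


def mann_whitney_u(group_a, group_b, method: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses exact null enumeration when both groups have n <= 8 and there are
    no cross-group ties; otherwise the tie-corrected normal approximation.
    Returns (U statistic for group_a, two-sided p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DegenerateInputError("both groups must be non-empty")
    if method == "auto":
        pooled = np.concatenate([a, b])
        small = max(a.size, b.size) <= 8
        method = "exact" if small and np.unique(pooled).size == pooled.size else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class DemingFit:
    """Total-least-squares line fit with errors in both variables."""

    slope: float
    intercept: float
    variance_ratio: float  # var(y errors) / var(x errors); 1 = orthogonal


def deming_fit(x, y, variance_ratio: float = 1.0) -> DemingFit:
    """Closed-form Deming estimator.

    Minimizes the sum of squared perpendicular (ratio-weighted) distances
    to the line.  ``variance_ratio`` is lambda = var(y error)/var(x error);
    lambda = 1 gives orthogonal regression, and as lambda grows the fit
    approaches ordinary least squares of y on x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise DegenerateInputError("deming_fit needs >= 2 (x, y) points")
    if not variance_ratio > 0:
        raise ValueError(f"variance_ratio must be > 0, got {variance_ratio!r}")
    lam = float(variance_ratio)
    xm, ym = x.mean(), y.mean()
    sxx = float(np.mean((x - xm) ** 2))
    syy = float(np.mean((y - ym) ** 2))
    sxy = float(np.mean((x - xm) * (y - ym)))
    if sxx == 0 and syy == 0:
        raise DegenerateInputError("all points coincide; line undefined")
    if sxy == 0:
        if syy > lam * sxx:
            raise DegenerateInputError("vertical line: slope unbounded for these data")
        slope = 0.0
    else:
        slope = (syy - lam * sxx + math.sqrt((syy - lam * sxx) ** 2 + 4 * lam * sxy**2)) / (
            2 * sxy
        )
    return DemingFit(slope=float(slope), intercept=float(ym - slope * xm), variance_ratio=lam)


@dataclass(frozen=True)
class GrowthFit:
    """Logistic growth fit od(t) = K / (1 + exp(-r (t - t0)))."""

    carrying_capacity: float  # K, OD units
    rate: float  # r, 1/h
    midpoint: float  # t0, h
    residual_norm: float


def _logistic(t, K, r, t0):
    return K / (1.0 + np.exp(-r * (t - t0)))


def logistic_growth_fit(time, od, seed: int | None = None) -> GrowthFit:
    """Nonlinear least squares fit of a logistic growth curve.

    Initialization is data-driven: K from the maximum OD, t0 from the time
    of half-maximum, r from the steepest local slope (max slope of a
    logistic is r*K/4).  Raises ``RuntimeError`` with diagnostics if the
    optimizer does not converge; a converged fit with ``rate < 0``
    (decreasing data) is returned as-is for the caller to flag.
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(od, dtype=float)
    if t.size != y.size or t.size < 4:
        raise DegenerateInputError("logistic fit needs >= 4 (time, od) points")
    k0 = float(y.max())
    if k0 <= 0:
        raise DegenerateInputError("OD values must include positive readings")
    t0_0 = float(t[np.argmin(np.abs(y - k0 / 2.0))])
    slopes = np.gradient(y, t)
    r0 = 4.0 * float(np.max(np.abs(slopes))) / k0
    r0 = r0 if r0 > 0 else 1.0
    try:
        popt, _ = optimize.curve_fit(
            _logistic, t, y, p0=[k0, r0, t0_0], maxfev=20_000
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"logistic growth fit did not converge (n={t.size}, "
            f"p0=[K={k0:.4g}, r={r0:.4g}, t0={t0_0:.4g}]): {exc}"
        ) from exc
    resid = y - _logistic(t, *popt)
    return GrowthFit(
        carrying_capacity=float(popt[0]),
        rate=float(popt[1]),
        midpoint=float(popt[2]),
        residual_norm=float(np.linalg.norm(resid)),
    )


def batch_summary(
    df: pd.DataFrame,
    value: str,
    by,
    n_boot: int = 1000,
    seed: int = 0,
    valid_col: str | None = None,
) -> pd.DataFrame:
    """Tidy per-group medians with bootstrap SEs.

    Groups ``df`` by the column(s) ``by`` and reports, per group, the
    number of records, the number passing ``valid_col`` (if given), and
    the median of ``value`` with its bootstrap standard error.  Rows are
    ordered by the sorted group keys so output is deterministic.
    """
    by = [by] if isinstance(by, str) else list(by)
    for col in by + [value] + ([valid_col] if valid_col else []):
        if col not in df.columns:
            raise KeyError(f"unknown column {col!r}")
    rows = []
    for i, (key, grp) in enumerate(df.groupby(by, sort=True)):
        key = key if isinstance(key, tuple) else (key,)
        vals = grp[value].to_numpy(dtype=float)
        if valid_col is not None:
            mask = grp[valid_col].to_numpy(dtype=bool)
            n_valid = int(mask.sum())
            vals = vals[mask]
        else:
            n_valid = len(grp)
        med, se = median_summary(vals, n_boot=n_boot, seed=seed + i)
        rows.append(dict(zip(by, key)) | {
            "n": len(grp), "n_valid": n_valid, "median": med, "median_se": se,
        })
    return pd.DataFrame(rows)
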