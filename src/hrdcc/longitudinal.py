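"""Per-animal time-series description of population percentages.

Trend fitting follows the analysis convention of robust outlier removal
before every fit: a robust (IRLS, Tukey biweight) cubic regression
standardises residuals by a robust scale estimate and flags outliers with
a false-discovery-rate rule at rate Q; the remaining points feed a cubic
polynomial, a four-knot cubic regression spline, or a straight line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats
from scipy.interpolate import LSQUnivariateSpline


@dataclass
class TrendFit:
    kind: str                   # "poly3" | "spline4" | "linear"
    coefficients: np.ndarray | None
    fitted: np.ndarray          # evaluated at the series' DIMs
    flags: np.ndarray           # outlier flags, aligned with the input
    residual_sd: float
    predict: object = None      # callable DIM -> fitted value


def _design(t: np.ndarray, degree: int) -> np.ndarray:
    return np.vander(t, degree + 1, increasing=True)


def rout_outliers(dims: np.ndarray, values: np.ndarray, q: float = 0.01,
                  ) -> np.ndarray:
    """Flag outliers from a robust cubic fit at FDR rate ``q``.

    An iteratively reweighted cubic (Tukey biweight) resists the outliers
    themselves; residuals are standardised by a MAD-based scale and
    two-sided t tail probabilities are screened with Benjamini-Hochberg
    at rate ``q``.  Series shorter than 10 points are returned unflagged
    with a warning.
    """
    dims = np.asarray(dims, dtype=float)
    values = np.asarray(values, dtype=float)
    if not 0.0 <= q < 0.5:
        raise ValueError("Q must lie in [0, 0.5)")
    n = len(values)
    flags = np.zeros(n, dtype=bool)
    if q == 0.0:
        return flags
    if n < 10:
        warnings.warn("series too short for outlier screening; no points flagged")
        return flags
    t = (dims - dims.mean()) / max(dims.std(), 1e-9)
    X = _design(t, 3)
    fit = sm.RLM(values, X, M=sm.robust.norms.TukeyBiweight()).fit()
    resid = values - fit.fittedvalues
    scale = stats.median_abs_deviation(resid, scale="normal")
    if scale <= 0:
        scale = max(np.std(resid), 1e-12)
    z = resid / scale
    df = max(n - 4, 1)
    pvals = 2.0 * stats.t.sf(np.abs(z), df)
    # Benjamini-Hochberg step-up
    order = np.argsort(pvals)
    ranked = pvals[order] <= q * (np.arange(1, n + 1) / n)
    k = np.flatnonzero(ranked)
    if len(k):
        flags[order[: k.max() + 1]] = True
    return flags


def fit_poly3(dims: np.ndarray, values: np.ndarray,
              flags: np.ndarray | None = None) -> TrendFit:
    """Least-squares cubic on unflagged points (power-basis coefficients,
    constant term first)."""
    dims = np.asarray(dims, dtype=float)
    values = np.asarray(values, dtype=float)
    keep = ~np.asarray(flags, dtype=bool) if flags is not None \
        else np.ones(len(dims), dtype=bool)
    x, y = dims[keep], values[keep]
    if len(x) < 5:
        raise ValueError("need at least 5 unflagged points for a cubic")
    if np.ptp(x) == 0:
        raise ValueError("rank-deficient design: all DIMs identical")
    poly = np.polynomial.Polynomial.fit(x, y, 3)
    coef = poly.convert().coef
    if len(coef) < 4:
        coef = np.pad(coef, (0, 4 - len(coef)))
    fitted = poly(dims)
    resid = values[keep] - poly(x)
    sd = float(np.std(resid, ddof=min(4, len(x) - 1)))
    return TrendFit("poly3", coef, fitted, ~keep, sd, predict=poly)


def fit_spline4(dims: np.ndarray, values: np.ndarray,
                flags: np.ndarray | None = None) -> TrendFit:
    """Cubic regression spline with four interior knots at the DIM
    quantiles {0.2, 0.4, 0.6, 0.8} of the unflagged points."""
    dims = np.asarray(dims, dtype=float)
    values = np.asarray(values, dtype=float)
    keep = ~np.asarray(flags, dtype=bool) if flags is not None \
        else np.ones(len(dims), dtype=bool)
    x, y = dims[keep], values[keep]
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    # average duplicate abscissae (pooled multi-animal series)
    ux, inverse = np.unique(x, return_inverse=True)
    if len(ux) < len(x):
        uy = np.bincount(inverse, weights=y) / np.bincount(inverse)
        x, y = ux, uy
    if len(x) < 8:
        raise ValueError("need at least 8 unflagged points for a 4-knot spline")
    knots = np.quantile(x, [0.2, 0.4, 0.6, 0.8])
    knots = np.unique(knots[(knots > x[0]) & (knots < x[-1])])
    spline = LSQUnivariateSpline(x, y, t=knots, k=3)
    fitted = spline(dims)
    resid = y - spline(x)
    dof = max(len(x) - (len(knots) + 4), 1)
    sd = float(np.sqrt(np.sum(resid ** 2) / dof))
    return TrendFit("spline4", None, fitted, ~keep, sd, predict=spline)


def fit_linear(dims: np.ndarray, values: np.ndarray,
               flags: np.ndarray | None = None) -> TrendFit:
    dims = np.asarray(dims, dtype=float)
    values = np.asarray(values, dtype=float)
    keep = ~np.asarray(flags, dtype=bool) if flags is not None \
        else np.ones(len(dims), dtype=bool)
    if keep.sum() < 2:
        raise ValueError("need at least 2 unflagged points")
    fit = stats.linregress(dims[keep], values[keep])
    fitted = fit.intercept + fit.slope * dims
    resid = values[keep] - (fit.intercept + fit.slope * dims[keep])
    return TrendFit("linear", np.array([fit.intercept, fit.slope]), fitted,
                    ~keep, float(np.std(resid, ddof=min(2, keep.sum() - 1))),
                    predict=lambda d: fit.intercept + fit.slope * np.asarray(d))


_FITTERS = {"poly3": fit_poly3, "spline4": fit_spline4, "linear": fit_linear}


def fit_trend(dims: np.ndarray, values: np.ndarray, kind: str = "spline4",
              q: float = 0.01) -> TrendFit:
    """Outlier screening at rate ``q`` followed by the requested fit."""
    flags = rout_outliers(dims, values, q)
    return _FITTERS[kind](dims, values, flags)


def per_animal_summary(values: np.ndarray) -> tuple[float, float, int]:
    """Arithmetic mean, sample SD (ddof=1) and n of a raw series."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 observations")
    return float(np.mean(values)), float(np.std(values, ddof=1)), len(values)
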