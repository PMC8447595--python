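"""Locally weighted polynomial regression (LOESS) over running order.

Classic Cleveland-style LOESS: for every target point the ``ceil(span * n)``
nearest neighbours are weighted by the tricube kernel and a degree-1 or -2
polynomial is fit by weighted least squares; the fit at the target point is
the local polynomial evaluated there.  No robustness iterations — drift
curves in MS data are smooth and outliers are handled upstream.

The span is the critical knob: too small overfits (and over-corrects noise
as if it were drift), too large misses real trends.  It is therefore a
mandatory, user-visible parameter everywhere this primitive is exposed.
"""

from __future__ import annotations

import numpy as np


class TooFewPoints(ValueError):
    """Raised when a series is too short to support a local fit."""


def fit_loess(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.75,
    degree: int = 2,
    min_points: int = 2,
) -> np.ndarray:
    """Fit LOESS to (x, y) and return fitted values at each x.

    Parameters
    ----------
    x:
        Strictly increasing predictor (running order).
    y:
        Observed log2 intensities, same length as x.
    span:
        Fraction of points in each local window, in (0, 1].
    degree:
        Local polynomial degree, 1 or 2.
    min_points:
        Minimum number of observations; fewer raises :class:`TooFewPoints`
        so the caller can fall back to a constant (median) fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < min_points:
        raise TooFewPoints(f"{n} observations < min_points={min_points}")
    if not (0 < span <= 1):
        raise ValueError("span must be in (0, 1]")
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")

    k = int(np.ceil(span * n))
    k = min(n, max(k, degree + 1))
    fitted = np.empty(n)
    order = np.arange(n)
    for i in range(n):
        d = np.abs(x - x[i])
        # stable k-nearest-neighbour window (ties broken by position)
        idx = order[np.argsort(d, kind="stable")[:k]]
        dmax = d[idx].max()
        if dmax == 0:
            fitted[i] = y[idx].mean()
            continue
        u = d[idx] / dmax
        w = (1.0 - u**3) ** 3
        pos = w > 0
        if pos.sum() <= degree:
            # degenerate window: fall back to the weighted mean
            fitted[i] = float(np.average(y[idx], weights=np.maximum(w, 1e-12)))
            continue
        # centre the predictor at the target point; the intercept is the fit
        coef = np.polynomial.polynomial.polyfit(
            x[idx] - x[i], y[idx], degree, w=np.sqrt(w)
        )
        fitted[i] = coef[0]
    return fitted
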