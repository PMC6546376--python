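"""Local-regression (LOESS) and kernel smoothers shared by the phenotype and
genome-scan modules.

The LOESS here is the classic tricube-weighted local polynomial of Cleveland
(no robustness iterations): for each evaluation point the ``ceil(span * n)``
nearest neighbours are weighted by ``(1 - (d/dmax)^3)^3`` and a degree-``d``
polynomial is fit by weighted least squares.  A local polynomial of degree
``d`` reproduces global polynomials of degree <= ``d`` exactly, which the
tests rely on.
"""

from __future__ import annotations

import numpy as np

__all__ = ["loess", "gaussian_kernel_smooth"]


def loess(
    x: np.ndarray,
    y: np.ndarray,
    x_eval: np.ndarray | None = None,
    span: float = 0.75,
    degree: int = 2,
) -> np.ndarray:
    """Tricube-weighted local polynomial fit evaluated at ``x_eval``.

    Parameters
    ----------
    x, y
        Observed points.  ``x`` need not be sorted; NaNs are not allowed.
    x_eval
        Evaluation grid; defaults to ``x`` itself.
    span
        Fraction of points in each local window, in ``(0, 1]``.
    degree
        Local polynomial degree (0 = moving weighted mean).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("loess input must not contain NaN")
    if not (0 < span <= 1):
        raise ValueError(f"span must be in (0, 1], got {span}")
    n = x.size
    if n < degree + 2:
        raise ValueError(f"need at least degree+2={degree + 2} points, got {n}")
    k = int(np.ceil(span * n))
    if k < degree + 2:
        raise ValueError(
            f"span {span} gives a local window of {k} points; "
            f"need at least {degree + 2} for a degree-{degree} fit"
        )
    if x_eval is None:
        x_eval = x
    x_eval = np.atleast_1d(np.asarray(x_eval, dtype=float))

    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    out = np.empty(x_eval.size, dtype=float)
    for i, x0 in enumerate(x_eval):
        d = np.abs(xs - x0)
        idx = np.argpartition(d, k - 1)[:k]
        dmax = d[idx].max()
        if dmax == 0:
            # all selected points coincide with x0
            out[i] = ys[idx].mean()
            continue
        w = (1 - (d[idx] / dmax) ** 3) ** 3
        w = np.clip(w, 0, None)
        out[i] = _wpolyfit_eval(xs[idx], ys[idx], w, degree, x0)
    return out


def _wpolyfit_eval(x, y, w, degree, x0):
    """Weighted least-squares polynomial fit evaluated at x0 (centered)."""
    xc = x - x0
    V = np.vander(xc, degree + 1, increasing=True)
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(V * sw[:, None], y * sw, rcond=None)
    return coef[0]


def gaussian_kernel_smooth(
    x: np.ndarray, y: np.ndarray, x_eval: np.ndarray | None = None, bandwidth: float = 1.0
) -> np.ndarray:
    """Nadaraya–Watson smoother with a Gaussian kernel of SD ``bandwidth``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if x_eval is None:
        x_eval = x
    x_eval = np.atleast_1d(np.asarray(x_eval, dtype=float))
    d = (x_eval[:, None] - x[None, :]) / bandwidth
    w = np.exp(-0.5 * d * d)
    return (w @ y) / w.sum(axis=1)
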