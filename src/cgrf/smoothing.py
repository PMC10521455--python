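"""Local polynomial (loess-style) smoothing of the target gene.

The target trajectory is modelled as y_t = f(t) + eps_t and f is estimated
by locally weighted polynomial regression with tricube weights. The
neighbourhood parameter alpha sets the weight bandwidth: for alpha <= 1 the
bandwidth at an evaluation point is the distance to its floor(alpha*T)-th
nearest time point; for alpha > 1 it is alpha times the largest distance.
Generalized cross-validation selects alpha on a grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["SmoothFit", "tricube", "loess_fit", "select_alpha"]


@dataclass(frozen=True)
class SmoothFit:
    """A fitted local-regression curve at the observed times.

    ``fitted + residuals`` reconstructs the observations exactly;
    ``hat_trace`` is the trace of the linear smoother matrix and feeds the
    GCV score ``(RSS/T) / (1 - hat_trace/T)^2``.
    """

    fitted: np.ndarray
    alpha: float
    degree: int
    hat_trace: float
    gcv: float
    residuals: np.ndarray


def tricube(x, u):
    """Tricube weight W(x; u) = (1 - (x/u)^3)^3 for 0 <= x < u, else 0."""
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0):
        raise ValueError("tricube distance x must be non-negative")
    if u <= 0:
        raise ValueError(f"tricube bandwidth u must be positive, got {u}")
    w = np.where(x_arr < u, (1.0 - (np.minimum(x_arr, u) / u) ** 3) ** 3, 0.0)
    return float(w) if np.isscalar(x) else w


def smoother_matrix(t, alpha: float, degree: int) -> np.ndarray:
    """T x T linear smoother matrix L with fitted = L @ y.

    Row j holds the equivalent-kernel weights of the local fit evaluated at
    t_j. Evaluation happens only at the observed times.
    """
    t = np.asarray(t, dtype=float)
    T = len(t)
    if degree not in (0, 1, 2):
        raise ValueError(f"degree must be 0, 1 or 2, got {degree}")
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    if T < degree + 2:
        raise ValueError(f"need at least degree+2={degree + 2} points, got {T}")

    L = np.zeros((T, T))
    for j in range(T):
        d = np.abs(t - t[j])
        if alpha <= 1:
            # bandwidth = distance to the floor(alpha*T)-th nearest point,
            # clamped so a polynomial of the requested degree is identifiable
            q = max(int(np.floor(alpha * T)), degree + 2)
            q = min(q, T)
            u = np.sort(d)[q - 1]
        else:
            u = d.max() * alpha
        if u <= 0:
            raise ValueError("degenerate bandwidth; increase alpha")
        w = tricube(d, u)
        pos = w > 0
        if pos.sum() < degree + 1:
            raise ValueError(
                f"only {int(pos.sum())} points receive positive weight at "
                f"t={t[j]} with alpha={alpha}; increase alpha"
            )
        dt = (t - t[j])[pos]
        B = np.vander(dt, degree + 1, increasing=True)  # columns 1, dt, dt^2
        Wb = w[pos]
        G = B.T * Wb @ B
        try:
            row = np.linalg.solve(G, B.T * Wb)[0]
        except np.linalg.LinAlgError:
            row = (np.linalg.pinv(G) @ (B.T * Wb))[0]
        L[j, pos] = row
    return L


def loess_fit(y, t, alpha: float, degree: int = 2) -> SmoothFit:
    """Fit a locally weighted polynomial of the given degree.

    The smoother is linear in y; its matrix trace enters the GCV score
    stored on the returned fit (``inf`` when the smoother interpolates).
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    if len(y) != len(t):
        raise ValueError(f"y and t lengths differ: {len(y)} vs {len(t)}")
    L = smoother_matrix(t, alpha, degree)
    fitted = L @ y
    residuals = y - fitted
    T = len(y)
    tr = float(np.trace(L))
    denom = 1.0 - tr / T
    rss = float(residuals @ residuals)
    gcv = (rss / T) / denom**2 if denom > 0 else float("inf")
    return SmoothFit(
        fitted=fitted,
        alpha=float(alpha),
        degree=int(degree),
        hat_trace=tr,
        gcv=gcv,
        residuals=residuals,
    )


def select_alpha(y, t, grid, degree: int = 2) -> tuple[float, list[SmoothFit]]:
    """Choose alpha on a grid by generalized cross-validation.

    GCV(alpha) = (1/T) * RSS / (1 - hat_trace/T)^2. Returns the grid argmin
    with exact ties broken toward the largest alpha, together with the fit
    at every grid point. An interpolating alpha (hat_trace == T) is scored
    +inf with a warning.
    """
    grid = [float(a) for a in grid]
    if not grid:
        raise ValueError("alpha grid must be non-empty")
    fits = [loess_fit(y, t, a, degree) for a in grid]
    for f in fits:
        if not np.isfinite(f.gcv):
            warnings.warn(
                f"alpha={f.alpha} interpolates the data (hat trace == T); "
                "its GCV is treated as infinite",
                stacklevel=2,
            )
    best = min(f.gcv for f in fits)
    # scores within float round-off of the minimum count as tied, and ties
    # resolve toward the smoothest (largest) alpha
    cut = best + max(1e-12, 1e-9 * abs(best))
    alpha_star = max(a for a, f in zip(grid, fits) if f.gcv <= cut)
    return alpha_star, fits


DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.02, 1.0001, 0.02), 2))
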