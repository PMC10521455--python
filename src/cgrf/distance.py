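"""Gene-to-target similarity: lock-step L_n distances and dynamic time warping.

Lock-step metrics compare series value-by-value at identical time indices
(Manhattan, Euclidean, general Minkowski). DTW instead minimises a
normalized cost over monotone warping paths through the alignment grid, so
shape similarity survives phase shifts. The metric registry is a documented
extension point; only the four metrics below are built in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .data_io import ExpressionMatrix
from .smoothing import SmoothFit

__all__ = [
    "DistanceTable",
    "lockstep",
    "dtw",
    "compute_target_distances",
    "SUPPORTED_METRICS",
]

SUPPORTED_METRICS = ("manhattan", "euclidean", "minkowski", "dtw")


@dataclass(frozen=True)
class DistanceTable:
    """Per-gene distances to the smoothed target curve."""

    gene_ids: tuple[str, ...]
    metric: str
    params: dict = field(default_factory=dict)
    distances: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        object.__setattr__(self, "distances", d)
        if len(d) != len(self.gene_ids):
            raise ValueError("distances and gene_ids must have equal length")
        if not np.all(np.isfinite(d)) or np.any(d < 0):
            raise ValueError("distances must be finite and non-negative")


def lockstep(Y, Z, n: int) -> float:
    """Minkowski-family lock-step distance (sum |Y_j - Z_j|^n)^(1/n).

    n=1 is Manhattan, n=2 Euclidean. Absolute differences keep odd orders
    well defined.
    """
    Y = np.asarray(Y, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if Y.shape != Z.shape:
        raise ValueError(
            f"lock-step distance needs equal lengths, got {len(Y)} and {len(Z)}"
        )
    if len(Y) < 1:
        raise ValueError("series must be non-empty")
    if n < 1 or int(n) != n:
        raise ValueError(f"order n must be a positive integer, got {n}")
    return float(np.sum(np.abs(Y - Z) ** n) ** (1.0 / n))


@njit(cache=False)
def _dtw_symmetric(y, z, window):  # pragma: no cover - exercised via dtw()
    n, m = len(y), len(z)
    INF = np.inf
    D = np.full((n, m), INF)
    D[0, 0] = 2.0 * abs(y[0] - z[0])
    for i in range(n):
        for j in range(m):
            if window >= 0 and abs(i - j) > window:
                continue
            if i == 0 and j == 0:
                continue
            c = abs(y[i] - z[j])
            best = INF
            if i > 0 and j > 0 and D[i - 1, j - 1] + 2.0 * c < best:
                best = D[i - 1, j - 1] + 2.0 * c
            if i > 0 and D[i - 1, j] + c < best:
                best = D[i - 1, j] + c
            if j > 0 and D[i, j - 1] + c < best:
                best = D[i, j - 1] + c
            D[i, j] = best
    return D[n - 1, m - 1] / (n + m)


@njit(cache=False)
def _dtw_asymmetric(y, z, window):  # pragma: no cover - exercised via dtw()
    # steps advancing the Y index carry weight 1, pure Z advances weight 0;
    # the path weight total is len(y) for every path.
    n, m = len(y), len(z)
    INF = np.inf
    D = np.full((n, m), INF)
    D[0, 0] = abs(y[0] - z[0])
    for i in range(n):
        for j in range(m):
            if window >= 0 and abs(i - j) > window:
                continue
            if i == 0 and j == 0:
                continue
            c = abs(y[i] - z[j])
            best = INF
            if i > 0 and j > 0 and D[i - 1, j - 1] + c < best:
                best = D[i - 1, j - 1] + c
            if i > 0 and D[i - 1, j] + c < best:
                best = D[i - 1, j] + c
            if j > 0 and D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = best
    return D[n - 1, m - 1] / n


def dtw(Y, Z, weighting: str = "symmetric", window: int | None = None) -> float:
    """Normalized dynamic time warping distance.

    Minimises sum_s d(p_s) w_s / sum_s w_s over monotone, continuous warping
    paths from (1,1) to (len(Y), len(Z)), with pointwise cost
    d(p_s) = |Y_u - Z_v|. Symmetric weighting gives diagonal steps weight 2
    and horizontal/vertical steps weight 1 (weight total len(Y)+len(Z) on
    every path); asymmetric weighting counts only steps advancing the Y
    index (weight total len(Y)). ``window`` optionally restricts the path to
    a Sakoe-Chiba band of half-width ``window``; the default is
    unconstrained.
    """
    Y = np.asarray(Y, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if len(Y) == 0 or len(Z) == 0:
        raise ValueError("DTW inputs must be non-empty")
    if weighting not in ("symmetric", "asymmetric"):
        raise ValueError(f"unknown DTW weighting: {weighting!r}")
    w = -1 if window is None else int(window)
    if w >= 0 and w < abs(len(Y) - len(Z)):
        raise ValueError("window too narrow to reach the grid corner")
    if weighting == "symmetric":
        return float(_dtw_symmetric(Y, Z, w))
    return float(_dtw_asymmetric(Y, Z, w))


def compute_target_distances(
    X: ExpressionMatrix,
    curve,
    metric: str,
    params: dict | None = None,
) -> DistanceTable:
    """Distance of every gene (target included) to the smoothed target curve.

    ``curve`` may be a :class:`~cgrf.smoothing.SmoothFit` or a plain length-T
    sequence. ``params`` supplies the Minkowski order ``n`` (default 3) or
    the DTW ``weighting``/``window``.
    """
    params = dict(params or {})
    if metric not in SUPPORTED_METRICS:
        raise ValueError(
            f"unknown metric {metric!r}; supported: {', '.join(SUPPORTED_METRICS)}"
        )
    z = np.asarray(curve.fitted if isinstance(curve, SmoothFit) else curve, dtype=float)
    if len(z) != X.n_times:
        raise ValueError(
            f"curve length {len(z)} does not match matrix timepoints {X.n_times}"
        )
    d = np.empty(X.n_genes)
    if metric == "dtw":
        weighting = params.setdefault("weighting", "symmetric")
        window = params.get("window")
        for i in range(X.n_genes):
            d[i] = dtw(X.values[i], z, weighting=weighting, window=window)
    else:
        n = {"manhattan": 1, "euclidean": 2}.get(metric, params.setdefault("n", 3))
        if metric == "minkowski":
            n = int(params["n"])
        diffs = np.abs(X.values - z[None, :])
        d = np.sum(diffs**n, axis=1) ** (1.0 / n)
    return DistanceTable(
        gene_ids=X.gene_ids, metric=metric, params=params, distances=d
    )
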