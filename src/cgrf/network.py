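"""Directed regulatory inference on the selected genes.

A first-order vector autoregression y(t+1) = A y(t) + B + eps(t) is fitted
by ordinary least squares; a nonzero a_ij is a lagged influence of gene j on
gene i. Edge strength is measured by the lagged partial correlation
sqrt(a_1k * a*_1k) * sgn(a*_1k), the geometric mean of the forward and
reverse regression coefficients, which equals the partial correlation
between y_i(t+1) and y_k(t) given the remaining lagged genes. A functional
("dynamic") correlation variant weights time points by a trapezoid rule so
unevenly spaced observations are handled gracefully; its partial
correlations come from the inverse correlation matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_io import ExpressionMatrix

__all__ = [
    "VARModel",
    "Edge",
    "EdgeList",
    "fit_var1",
    "lagged_partial_correlation",
    "lagged_partial_correlation_matrix",
    "dynamic_inner_product",
    "dynamic_correlation_matrix",
    "dynamic_partial_correlation",
    "top_edges",
]


@dataclass(frozen=True)
class VARModel:
    """OLS-fitted VAR(1). ``A[i, j]`` is the effect of gene j at t on gene i
    at t+1; ``B`` is the intercept; ``residual_cov`` the residual covariance."""

    gene_ids: tuple[str, ...]
    A: np.ndarray
    B: np.ndarray
    residual_cov: np.ndarray
    rank_deficient: bool


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    weight: float
    sign: str
    rank: int


@dataclass(frozen=True)
class EdgeList:
    edges: tuple[Edge, ...]
    directed: bool

    def to_records(self) -> list[dict]:
        return [
            {
                "rank": e.rank,
                "source": e.source,
                "target": e.target,
                "weight": e.weight,
                "sign": e.sign,
            }
            for e in self.edges
        ]


def _lag_design(X_sel: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(Y_past, Y_future) as (T-1) x p arrays."""
    V = X_sel.values
    if X_sel.n_times < 3:
        raise ValueError(f"need at least 3 time points, got {X_sel.n_times}")
    if np.any(np.all(V == V[:, :1], axis=1)):
        bad = X_sel.gene_ids[int(np.argmax(np.all(V == V[:, :1], axis=1)))]
        raise ValueError(f"gene {bad!r} is constant; VAR regression is degenerate")
    return V[:, :-1].T, V[:, 1:].T


def fit_var1(X_sel: ExpressionMatrix) -> VARModel:
    """OLS estimate of the VAR(1) coefficients with intercept.

    Regresses Y_future = [y(2), ..., y(T)] on Y_past = [y(1), ..., y(T-1)].
    When the Gram matrix is singular (p >= T-1, common for gene panels) the
    Moore-Penrose pseudoinverse is used and ``rank_deficient`` is set, with
    a warning. The residual covariance uses denominator T-1-(p+1); when that
    is non-positive the uncorrected second-moment matrix is reported with a
    warning.
    """
    Y_past, Y_future = _lag_design(X_sel)
    n_obs, p = Y_past.shape
    Z = np.hstack([Y_past, np.ones((n_obs, 1))])
    G = Z.T @ Z
    rank_deficient = np.linalg.matrix_rank(G) < p + 1
    if rank_deficient:
        warnings.warn(
            f"VAR design is rank deficient (p={p}, T={X_sel.n_times}); "
            "using the Moore-Penrose pseudoinverse",
            stacklevel=2,
        )
        coef = np.linalg.pinv(Z) @ Y_future
    else:
        coef = np.linalg.solve(G, Z.T @ Y_future)
    A = coef[:p].T
    B = coef[p].copy()
    resid = Y_future - Z @ coef
    dof = n_obs - (p + 1)
    if dof > 0:
        residual_cov = resid.T @ resid / dof
    else:
        warnings.warn(
            "no residual degrees of freedom; reporting the uncorrected "
            "residual second-moment matrix",
            stacklevel=2,
        )
        residual_cov = resid.T @ resid / n_obs
    return VARModel(
        gene_ids=X_sel.gene_ids,
        A=A,
        B=B,
        residual_cov=residual_cov,
        rank_deficient=bool(rank_deficient),
    )


def lagged_partial_correlation(
    X_sel: ExpressionMatrix,
    target_index: int,
    source_index: int,
    allow_rank_deficient: bool = False,
) -> float:
    """Lagged partial correlation source -> target via two regressions.

    a_1k is the coefficient of y_k(t) in the regression of y_i(t+1) on all
    lagged genes; a*_1k is the coefficient of y_i(t+1) in the regression of
    y_k(t) on y_i(t+1) and the other lagged genes. The result
    sqrt(a_1k * a*_1k) * sgn(a*_1k) lies in [-1, 1]; the product is
    non-negative up to round-off (asserted).
    """
    Y_past, Y_future = _lag_design(X_sel)
    n_obs, p = Y_past.shape
    i, k = int(target_index), int(source_index)

    def _ols(y, Xd):
        D = np.hstack([Xd, np.ones((n_obs, 1))])
        if np.linalg.matrix_rank(D) < D.shape[1]:
            if not allow_rank_deficient:
                raise np.linalg.LinAlgError(
                    "rank-deficient regression; enable allow_rank_deficient "
                    "to use a pseudoinverse solution"
                )
            return np.linalg.pinv(D) @ y
        return np.linalg.lstsq(D, y, rcond=None)[0]

    beta_fwd = _ols(Y_future[:, i], Y_past)
    a = beta_fwd[k]
    others = [j for j in range(p) if j != k]
    Xd_rev = np.hstack([Y_future[:, i : i + 1], Y_past[:, others]])
    beta_rev = _ols(Y_past[:, k], Xd_rev)
    a_star = beta_rev[0]
    prod = a * a_star
    assert prod >= -1e-10, f"forward/reverse coefficient product negative: {prod}"
    return float(np.sqrt(max(prod, 0.0)) * np.sign(a_star))


def lagged_partial_correlation_matrix(X_sel: ExpressionMatrix) -> np.ndarray:
    """All lagged partial correlations at once.

    Entry ``P[i, k]`` is the partial correlation between y_i(t+1) and
    y_k(t) given the other lagged genes, computed from the precision matrix
    of the joint (p+1)-variable sample covariance — algebraically identical
    to the two-regression definition.
    """
    Y_past, Y_future = _lag_design(X_sel)
    n_obs, p = Y_past.shape
    P = np.empty((p, p))
    for i in range(p):
        joint = np.column_stack([Y_future[:, i], Y_past])
        V = np.cov(joint, rowvar=False)
        try:
            omega = np.linalg.inv(V)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "joint covariance is singular; reduce the gene set or add "
                "observations"
            ) from None
        P[i, :] = -omega[0, 1:] / np.sqrt(omega[0, 0] * np.diag(omega)[1:])
    return P


def dynamic_inner_product(g, h, times) -> float:
    """Trapezoid-weighted functional inner product.

    <g, h> = sum_j g(t_j) h(t_j) (t_{j+1} - t_{j-1}) / (2T) with one-sided
    boundary conventions t_0 := t_1 and t_{T+1} := t_T. Bilinear and
    symmetric.
    """
    g = np.asarray(g, dtype=float)
    h = np.asarray(h, dtype=float)
    if g.shape != h.shape:
        raise ValueError(f"series lengths differ: {len(g)} vs {len(h)}")
    if len(g) < 2:
        raise ValueError("need at least two time points")
    return float(np.sum(g * h * _functional_weights(times)))


def _functional_weights(times) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    T = len(t)
    pad = np.concatenate([[t[0]], t, [t[-1]]])
    return (pad[2:] - pad[:-2]) / (2.0 * T)


def dynamic_correlation_matrix(X_sel: ExpressionMatrix) -> np.ndarray:
    """Functional ("dynamic") correlation matrix of the selected genes.

    Each series is standardized under the functional inner product —
    centred by <f, 1> and scaled by sqrt(<f - <f,1>, f - <f,1>>) — so the
    diagonal is exactly 1 and the matrix is symmetric.
    """
    w = _functional_weights(X_sel.times)
    F = X_sel.values
    constant = np.all(F == F[:, :1], axis=1)
    if constant.any():
        bad = X_sel.gene_ids[int(np.argmax(constant))]
        raise ValueError(f"gene {bad!r} is constant (zero variance)")
    means = F @ w  # <f, 1>
    Fc = F - means[:, None]
    var = (Fc**2) @ w
    if np.any(var <= 0):
        bad = X_sel.gene_ids[int(np.argmax(var <= 0))]
        raise ValueError(f"gene {bad!r} has zero functional variance")
    S = Fc / np.sqrt(var)[:, None]
    corr = (S * w) @ S.T
    return (corr + corr.T) / 2.0


def dynamic_partial_correlation(corr: np.ndarray, shrinkage: float = 0.0) -> np.ndarray:
    """Partial correlations from a correlation matrix.

    pcor_kl = -omega_kl / sqrt(omega_kk * omega_ll) with omega the inverse of
    ``corr``; the unit diagonal is restored. A singular input raises with a
    hint to pass ``shrinkage`` > 0, which blends ``corr`` toward the
    identity as (1 - shrinkage) * corr + shrinkage * I first.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    if shrinkage:
        if not 0 <= shrinkage <= 1:
            raise ValueError("shrinkage must lie in [0, 1]")
        corr = (1.0 - shrinkage) * corr + shrinkage * np.eye(len(corr))
    sign, logdet = np.linalg.slogdet(corr)
    if sign <= 0 or logdet < -700:
        raise np.linalg.LinAlgError(
            "correlation matrix is singular or indefinite; retry with a "
            "positive shrinkage intensity"
        )
    omega = np.linalg.inv(corr)
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    return (pcor + pcor.T) / 2.0


def top_edges(
    weights: np.ndarray,
    gene_ids,
    n_top: int = 150,
    directed: bool = True,
    include_self_loops: bool = False,
) -> EdgeList:
    """Rank edges by descending absolute weight.

    For directed input ``weights[i, j]`` is the weight of edge j -> i
    (source column, target row), matching the VAR coefficient convention;
    for undirected input only the upper triangle is ranked. Exact-zero
    weights are absent edges. Ties in |weight| break lexicographically on
    (source, target); self-loops are excluded unless requested. If fewer
    than ``n_top`` edges exist, all are returned.
    """
    if n_top < 1:
        raise ValueError(f"n_top must be >= 1, got {n_top}")
    W = np.asarray(weights, dtype=float)
    gene_ids = list(gene_ids)
    p = len(gene_ids)
    if W.shape != (p, p):
        raise ValueError("weights must be p x p aligned with gene_ids")
    entries = []
    for i in range(p):
        for j in range(p):
            if i == j and not include_self_loops:
                continue
            if not directed and j <= i:
                continue
            w = W[i, j]
            if w == 0.0:
                continue
            source, target = (gene_ids[j], gene_ids[i]) if directed else (
                gene_ids[i],
                gene_ids[j],
            )
            entries.append((-abs(w), source, target, w))
    entries.sort()
    edges = tuple(
        Edge(
            source=s,
            target=t,
            weight=float(w),
            sign="+" if w > 0 else "-",
            rank=r + 1,
        )
        for r, (_, s, t, w) in enumerate(entries[:n_top])
    )
    return EdgeList(edges=edges, directed=directed)
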