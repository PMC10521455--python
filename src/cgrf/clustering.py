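"""Fuzzy C-means clustering of gene trajectories.

Soft clustering is the dimension-reduction step of the framework: genes with
overlapping temporal programmes receive graded memberships rather than hard
labels. The objective minimised is

    L(K, m) = sum_k sum_i u_ki^m * ||y_i - c_k||^2,   sum_k u_ki = 1,

with fuzzifier m > 1 controlling softness. The number of clusters can be
guided by the Gap statistic (within-cluster dispersion of the hardened
partition versus reference data with no cluster structure).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .data_io import ExpressionMatrix

__all__ = [
    "ClusterModel",
    "GapCurve",
    "estimate_fuzzifier",
    "fuzzy_cmeans",
    "gap_statistic",
    "select_cluster_of",
]


@dataclass(frozen=True)
class ClusterModel:
    """Fitted fuzzy C-means model.

    ``memberships`` is K x N with columns summing to one; ``centroids`` is
    K x T. ``objective_trace`` holds L(K, m) after each alternating update
    and is non-increasing.
    """

    K: int
    m: float
    memberships: np.ndarray
    centroids: np.ndarray
    objective_trace: tuple[float, ...]
    seed: int
    gene_ids: tuple[str, ...]

    def hard_labels(self) -> np.ndarray:
        """Argmax membership per gene; ties resolve to the smallest index."""
        return np.argmax(self.memberships, axis=0)


@dataclass(frozen=True)
class GapCurve:
    """Gap statistic over a range of cluster numbers."""

    k_values: tuple[int, ...]
    gap: np.ndarray
    sd: np.ndarray
    k_hat: int


def estimate_fuzzifier(n_genes: int, n_timepoints: int) -> float:
    """Data-size based fuzzifier estimate.

    Uses the empirical relation of Schwammle & Jensen (2010), a function of
    the number of objects N (genes) and the feature dimension D (timepoints):

        m = 1 + (1418/N + 22.05) D^-2
              + (12.33/N + 0.243) D^(-0.0406 ln N - 0.1134)

    Always returns a value > 1; decreasing in D for fixed N.
    """
    if n_genes < 2 or n_timepoints < 1:
        raise ValueError(
            f"need n_genes >= 2 and n_timepoints >= 1, got {n_genes}, {n_timepoints}"
        )
    N, D = float(n_genes), float(n_timepoints)
    return 1.0 + (1418.0 / N + 22.05) * D ** -2.0 + (
        12.33 / N + 0.243
    ) * D ** (-0.0406 * math.log(N) - 0.1134)


def _objective(values: np.ndarray, U: np.ndarray, C: np.ndarray, m: float) -> float:
    d2 = cdist(C, values, metric="sqeuclidean")
    return float(np.sum(U**m * d2))


def _membership_update(d2: np.ndarray, m: float) -> np.ndarray:
    """Memberships from squared distances: u_ki oc d2_ki^(-1/(m-1)).

    Computed on distance ratios d2/d2_min so small fuzzifiers (steep
    exponents) neither overflow nor underflow whole columns; genes sitting
    (numerically) on >=1 centroid split evenly among those.
    """
    d2_min = d2.min(axis=0, keepdims=True)
    on_centroid = d2 <= 0.0
    hit = on_centroid.any(axis=0)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        inv = (d2 / np.where(d2_min > 0, d2_min, 1.0)) ** (-1.0 / (m - 1.0))
        U = inv / inv.sum(axis=0, keepdims=True)
    if hit.any():
        U[:, hit] = on_centroid[:, hit] / on_centroid[:, hit].sum(
            axis=0, keepdims=True
        )
    return U


def _kmeanspp_init(values: np.ndarray, K: int, m: float, rng) -> np.ndarray:
    """Initial memberships from k-means++ (D^2-sampled) seed genes."""
    idx = [int(rng.integers(len(values)))]
    for _ in range(K - 1):
        d2 = cdist(values[idx], values, metric="sqeuclidean").min(axis=0)
        total = d2.sum()
        if total <= 0:  # all genes coincide with a chosen seed
            idx.append(int(rng.integers(len(values))))
            continue
        idx.append(int(rng.choice(len(values), p=d2 / total)))
    return _membership_update(cdist(values[idx], values, "sqeuclidean"), m)


def fuzzy_cmeans(
    X: ExpressionMatrix,
    K: int,
    m: float,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
    n_init: int = 10,
    init: str = "kmeans++",
) -> ClusterModel:
    """Alternating-update fuzzy C-means with squared Euclidean distance.

    Initial memberships come either from k-means++ (D^2-sampled) seed genes
    (default) or from a per-gene symmetric Dirichlet(1) draw
    (``init="dirichlet"``); centroids are u^m-weighted means and memberships
    are refreshed from centroid distances with exponent 2/(m-1). Iteration
    stops when the absolute objective change falls below ``tol`` or after
    ``max_iter`` sweeps. The alternating updates only find a local optimum,
    so ``n_init`` restarts are run from sub-seeds spawned deterministically
    from ``seed`` and the solution with the lowest final objective is kept.
    Identical seed yields identical results.
    """
    if n_init < 1:
        raise ValueError(f"n_init must be >= 1, got {n_init}")
    sub_seeds = np.random.SeedSequence(seed).generate_state(n_init) % (2**31)
    best: ClusterModel | None = None
    for s in sub_seeds:
        model = _fuzzy_cmeans_once(X, K, m, max_iter, tol, int(s), init)
        if best is None or model.objective_trace[-1] < best.objective_trace[-1]:
            best = model
    return ClusterModel(
        K=best.K, m=best.m, memberships=best.memberships,
        centroids=best.centroids, objective_trace=best.objective_trace,
        seed=int(seed), gene_ids=best.gene_ids,
    )


def _fuzzy_cmeans_once(
    X: ExpressionMatrix,
    K: int,
    m: float,
    max_iter: int,
    tol: float,
    seed: int,
    init: str = "kmeans++",
) -> ClusterModel:
    N = X.n_genes
    if not 1 <= K <= N:
        raise ValueError(f"K must be in [1, {N}], got {K}")
    if m <= 1:
        raise ValueError(f"fuzzifier m must be > 1, got {m}")
    if tol <= 0:
        raise ValueError(f"tol must be positive, got {tol}")

    rng = np.random.default_rng(seed)
    values = X.values
    if init == "kmeans++":
        U = _kmeanspp_init(values, K, m, rng)
    elif init == "dirichlet":
        U = rng.dirichlet(np.ones(K), size=N).T  # K x N
    else:
        raise ValueError(f"unknown init: {init!r}")
    trace: list[float] = []
    prev = np.inf
    for _ in range(max_iter):
        Um = U**m
        C = (Um @ values) / Um.sum(axis=1, keepdims=True)
        d2 = cdist(C, values, metric="sqeuclidean")
        U = _membership_update(d2, m)
        obj = _objective(values, U, C, m)
        trace.append(obj)
        if abs(prev - obj) < tol:
            break
        prev = obj
    return ClusterModel(
        K=K,
        m=float(m),
        memberships=U,
        centroids=C,
        objective_trace=tuple(trace),
        seed=int(seed),
        gene_ids=X.gene_ids,
    )


def _within_dispersion(values: np.ndarray, labels: np.ndarray, K: int) -> float:
    """Total within-cluster sum of squared distances to hardened centroids."""
    W = 0.0
    for k in range(K):
        members = values[labels == k]
        if len(members) == 0:
            continue
        W += float(np.sum((members - members.mean(axis=0)) ** 2))
    return W


def gap_statistic(
    X: ExpressionMatrix,
    k_max: int,
    B: int,
    m: float,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
    n_init: int = 3,
) -> GapCurve:
    """Gap statistic over k = 1..k_max using hardened fuzzy partitions.

    For each k, ``gap(k) = mean_b log W*_kb - log W_k`` where W is the total
    within-cluster dispersion of the hardened clustering and the B reference
    datasets are drawn uniformly over each feature's observed range. ``sd``
    carries the reference standard errors ``sd_b(log W*) * sqrt(1 + 1/B)``.
    ``k_hat`` is the argmax of the gap; the full curve is returned so an
    elbow can be preferred when the argmax overshoots.
    """
    if k_max < 1:
        raise ValueError(f"k_max must be >= 1, got {k_max}")
    if B < 1:
        raise ValueError(f"B must be >= 1, got {B}")
    values = X.values
    lo, hi = values.min(axis=0), values.max(axis=0)
    ss = np.random.SeedSequence(seed)
    fit_seeds, ref_seeds = ss.spawn(2)
    fit_ints = fit_seeds.generate_state(k_max) % (2**31)
    ref_rng = np.random.default_rng(ref_seeds)
    refs = [
        ref_rng.uniform(lo, hi, size=values.shape) for _ in range(B)
    ]
    ref_ints = ref_seeds.generate_state(k_max * B) % (2**31)

    tiny = np.finfo(float).tiny
    gaps, sds = [], []
    for ki, k in enumerate(range(1, k_max + 1)):
        model = fuzzy_cmeans(
            X, k, m, max_iter=max_iter, tol=tol, seed=int(fit_ints[ki]),
            n_init=n_init,
        )
        logW = np.log(max(_within_dispersion(values, model.hard_labels(), k), tiny))
        logWstar = np.empty(B)
        for b, ref in enumerate(refs):
            ref_X = ExpressionMatrix(
                tuple(f"ref{i}" for i in range(len(ref))), X.times, ref
            )
            rmodel = fuzzy_cmeans(
                ref_X, k, m, max_iter=max_iter, tol=tol,
                seed=int(ref_ints[ki * B + b]), n_init=n_init,
            )
            logWstar[b] = np.log(
                max(_within_dispersion(ref, rmodel.hard_labels(), k), tiny)
            )
        gaps.append(float(logWstar.mean() - logW))
        sds.append(float(logWstar.std(ddof=0) * math.sqrt(1.0 + 1.0 / B)))
    gaps_arr = np.asarray(gaps)
    k_values = tuple(range(1, k_max + 1))
    return GapCurve(
        k_values=k_values,
        gap=gaps_arr,
        sd=np.asarray(sds),
        k_hat=k_values[int(np.argmax(gaps_arr))],
    )


def select_cluster_of(model: ClusterModel, X: ExpressionMatrix, gene_id: str) -> int:
    """Cluster index (0-based) with the largest membership for ``gene_id``.

    Ties break toward the smallest index.
    """
    i = X.index_of(gene_id)
    return int(np.argmax(model.memberships[:, i]))
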