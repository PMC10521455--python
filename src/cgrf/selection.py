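"""Significant-gene selection by incremental Wilcoxon rank agreement.

Genes of the target's cluster are sorted by ascending distance to the
smoothed target, and their ranks among ALL genes are compared against the
ordinal ranking 1..n with a paired Wilcoxon signed-rank test. Growing n from
``start``, the procedure stops at the first significant test; the
significant set is the last non-significant n. Genes of other clusters whose
distance falls within the significant genes' range are rescued, so no
relevant gene is lost to a cluster boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .distance import DistanceTable

__all__ = [
    "SelectionResult",
    "global_ranks",
    "wilcoxon_signed_rank",
    "significant_count",
    "rescue_genes",
    "select_genes",
]

_EXACT_N_MAX = 25


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the selection stage for one cluster."""

    cluster_index: int
    significant_ids: tuple[str, ...]
    n_sig: int
    p_trace: tuple[tuple[int, float], ...]
    rescued_ids: tuple[str, ...]
    threshold_distance: float


def global_ranks(table: DistanceTable) -> np.ndarray:
    """Rank 1 = smallest distance over all genes; ties keep input order."""
    order = np.argsort(table.distances, kind="stable")
    ranks = np.empty(len(order), dtype=int)
    ranks[order] = np.arange(1, len(order) + 1)
    return ranks


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p by convolution over all 2^n sign assignments.

    Midranks are multiples of 1/2, so doubling makes the rank-sum lattice
    integral and the null distribution of W+ is an exact integer DP.
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    w2 = int(np.rint(2.0 * w_plus))
    n_assignments = 2.0 ** len(r2)
    p_le = counts[: w2 + 1].sum() / n_assignments
    p_ge = counts[w2:].sum() / n_assignments
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(a, b, zero_policy: str = "discard") -> float:
    """Two-sided paired Wilcoxon signed-rank p-value on differences a - b.

    Zero differences are discarded before ranking (classic Wilcoxon). The
    null distribution is exact (full sign-assignment enumeration via DP,
    ties handled through midranks) for effective n <= 25 and a normal
    approximation with tie correction above. All-zero differences give
    p = 1.
    """
    if zero_policy != "discard":
        raise ValueError(f"unsupported zero policy: {zero_policy!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"paired samples differ in length: {len(a)} vs {len(b)}")
    if len(a) < 1:
        raise ValueError("need at least one pair")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= _EXACT_N_MAX:
        return _exact_two_sided_p(ranks, w_plus)
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if sigma2 <= 0:
        return 1.0
    z = (w_plus - mu) / np.sqrt(sigma2)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def significant_count(
    cluster_global_ranks,
    start: int = 10,
    step: int = 1,
    threshold: float = 0.05,
) -> tuple[int, list[tuple[int, float]]]:
    """Grow n from ``start`` until the rank-agreement test turns significant.

    ``cluster_global_ranks`` are the global ranks of the cluster's genes in
    ascending-distance order. For each tested n the first n global ranks are
    compared against the ordinal ranks 1..n; the procedure stops at the
    first p < threshold and reports the last non-significant n. If the test
    never turns significant, every cluster gene is significant.
    """
    if start < 2:
        raise ValueError(f"start must be >= 2, got {start}")
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    ranks = np.asarray(cluster_global_ranks, dtype=float)
    C = len(ranks)
    p_trace: list[tuple[int, float]] = []
    if C < start:
        warnings.warn(
            f"cluster has only {C} genes (< start={start}); "
            "keeping the whole cluster",
            stacklevel=2,
        )
        return C, p_trace
    for n in range(start, C + 1, step):
        p = wilcoxon_signed_rank(ranks[:n], np.arange(1, n + 1))
        p_trace.append((n, p))
        if p < threshold:
            return n - step, p_trace
    return C, p_trace


def rescue_genes(
    table: DistanceTable,
    labels,
    cluster_index: int,
    significant_ids,
) -> list[str]:
    """Genes outside the cluster within the significant distance range.

    Returns every gene with a different hard label whose distance is at most
    the maximum distance among ``significant_ids`` (inclusive boundary),
    ordered by ascending distance.
    """
    significant_ids = list(significant_ids)
    if not significant_ids:
        raise ValueError("significant gene set is empty; nothing to rescue against")
    labels = np.asarray(labels)
    if len(labels) != len(table.gene_ids):
        raise ValueError("labels must align with the distance table")
    idx = {g: i for i, g in enumerate(table.gene_ids)}
    threshold = max(table.distances[idx[g]] for g in significant_ids)
    candidates = [
        (table.distances[i], g)
        for i, g in enumerate(table.gene_ids)
        if labels[i] != cluster_index and table.distances[i] <= threshold
    ]
    candidates.sort(key=lambda t: t[0])
    return [g for _, g in candidates]


def select_genes(
    table: DistanceTable,
    labels,
    cluster_index: int,
    start: int = 10,
    step: int = 1,
    threshold: float = 0.05,
) -> SelectionResult:
    """Run the full selection stage for the target's cluster.

    Sorts the cluster's genes by ascending distance, determines the
    significant count, and rescues close genes from other clusters.
    """
    labels = np.asarray(labels)
    order = np.argsort(table.distances, kind="stable")
    all_ranks = global_ranks(table)
    cluster_sorted = [i for i in order if labels[i] == cluster_index]
    if not cluster_sorted:
        raise ValueError(f"cluster {cluster_index} contains no genes")
    n_sig, p_trace = significant_count(
        all_ranks[cluster_sorted], start=start, step=step, threshold=threshold
    )
    n_sig = max(n_sig, 1)  # the nearest cluster gene always stays selected
    significant_ids = tuple(table.gene_ids[i] for i in cluster_sorted[:n_sig])
    rescued = rescue_genes(table, labels, cluster_index, significant_ids)
    idx = {g: i for i, g in enumerate(table.gene_ids)}
    threshold_distance = max(table.distances[idx[g]] for g in significant_ids)
    return SelectionResult(
        cluster_index=int(cluster_index),
        significant_ids=significant_ids,
        n_sig=len(significant_ids),
        p_trace=tuple(p_trace),
        rescued_ids=tuple(rescued),
        threshold_distance=float(threshold_distance),
    )
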