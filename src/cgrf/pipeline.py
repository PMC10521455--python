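"""End-to-end orchestration: filter, cluster, smooth, rank, select, infer.

The stages mirror the framework's logical flow: (1) cluster the standardized
genes and pick the target's cluster, (2) smooth the target, (3) rank every
gene by its distance to the smoothed curve, (4) grow the significant set by
the Wilcoxon rank-agreement rule, (5) rescue close genes from other
clusters, (6) fit a VAR(1) on the selected panel and rank edges by (lagged
and/or dynamic) partial correlation. Every stage writes a TSV artifact and a
manifest records all resolved parameters; re-running from the manifest
reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .clustering import estimate_fuzzifier, fuzzy_cmeans, gap_statistic, select_cluster_of
from .data_io import filter_zero_variance, read_expression_matrix, standardize_genes
from .distance import compute_target_distances
from .network import (
    dynamic_correlation_matrix,
    dynamic_partial_correlation,
    fit_var1,
    lagged_partial_correlation_matrix,
    top_edges,
)
from .selection import global_ranks, select_genes
from .smoothing import DEFAULT_ALPHA_GRID, loess_fit, select_alpha

logger = logging.getLogger("cgrf")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Flat configuration for one pipeline run.

    ``k``, ``fuzzifier`` and ``alpha`` accept the string ``"auto"``: k is
    then chosen by the Gap statistic argmax, the fuzzifier by the data-size
    relation, and alpha by GCV on the default grid.
    """

    input: str
    target: str
    out: str
    k: int | str = "auto"
    fuzzifier: float | str = "auto"
    degree: int = 2
    alpha: float | str = "auto"
    metric: str = "dtw"
    minkowski_n: int = 3
    dtw_weighting: str = "symmetric"
    start: int = 10
    step: int = 1
    p_threshold: float = 0.05
    mode: str = "both"
    top_n_edges: int = 150
    dynamic_shrinkage: float = 0.05
    k_max: int = 12
    gap_b: int = 20
    seed: int = 0
    delimiter: str | None = None

    _INT_FIELDS = ("degree", "minkowski_n", "start", "step", "top_n_edges",
                   "k_max", "gap_b", "seed")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Parse a flat ``key: value`` text file (``#`` starts a comment)."""
        raw: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if ":" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key: value'")
                key, value = line.split(":", 1)
                raw[key.strip().replace("-", "_")] = value.strip()
        return cls.from_mapping(raw)

    @classmethod
    def from_mapping(cls, raw: dict) -> "PipelineConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict = {}
        for key, value in raw.items():
            if key in cls._INT_FIELDS:
                kwargs[key] = int(value)
            elif key in ("k",):
                kwargs[key] = value if value == "auto" else int(value)
            elif key in ("fuzzifier", "alpha"):
                kwargs[key] = value if value == "auto" else float(value)
            elif key in ("p_threshold", "dynamic_shrinkage"):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_manifest(self) -> str:
        lines = [f"# cgrf {__version__} run manifest; re-runnable as a config"]
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if value is None:
                continue
            lines.append(f"{f.name}: {value}")
        return "\n".join(lines) + "\n"


def _write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write every artifact under ``config.out``.

    Returns a dict of the in-memory stage results keyed by stage name.
    Identical config and seed produce byte-identical outputs.
    """
    os.makedirs(config.out, exist_ok=True)
    out = lambda name: os.path.join(config.out, name)  # noqa: E731

    X_raw = read_expression_matrix(config.input, delimiter=config.delimiter)
    logger.info("loaded %d genes x %d timepoints", X_raw.n_genes, X_raw.n_times)

    X_nz, removed = filter_zero_variance(X_raw)
    logger.info("removed %d zero-variance genes, %d remain", len(removed), X_nz.n_genes)
    if config.target not in X_nz.gene_ids:
        raise ValueError(
            f"target gene {config.target!r} absent after zero-variance filtering"
        )
    X = standardize_genes(X_nz)

    # -- clustering ---------------------------------------------------------
    m = (
        estimate_fuzzifier(X.n_genes, X.n_times)
        if config.fuzzifier == "auto"
        else float(config.fuzzifier)
    )
    resolved = dataclasses.replace(config, fuzzifier=m)
    if config.k == "auto":
        curve = gap_statistic(X, k_max=config.k_max, B=config.gap_b, m=m,
                              seed=config.seed)
        _write_tsv(
            pd.DataFrame(
                {"k": curve.k_values, "gap": curve.gap, "sd": curve.sd}
            ),
            out("gap.tsv"),
        )
        K = curve.k_hat
        logger.info("gap statistic chose k=%d", K)
    else:
        K = int(config.k)
    resolved = dataclasses.replace(resolved, k=K)
    model = fuzzy_cmeans(X, K, m, seed=config.seed)
    _write_tsv(
        pd.DataFrame(
            model.memberships.T,
            columns=[f"cluster_{k}" for k in range(K)],
        ).assign(gene_id=list(X.gene_ids))[
            ["gene_id"] + [f"cluster_{k}" for k in range(K)]
        ],
        out("memberships.tsv"),
    )
    _write_tsv(
        pd.DataFrame(model.centroids, columns=[str(t) for t in X.times]).assign(
            cluster=range(K)
        )[["cluster"] + [str(t) for t in X.times]],
        out("centroids.tsv"),
    )
    cluster_index = select_cluster_of(model, X, config.target)
    labels = model.hard_labels()
    logger.info(
        "target %r is in cluster %d (%d genes)",
        config.target, cluster_index, int((labels == cluster_index).sum()),
    )

    # -- smoothing ----------------------------------------------------------
    y_target = X.row(config.target)
    if config.alpha == "auto":
        alpha, _ = select_alpha(y_target, X.times, DEFAULT_ALPHA_GRID, config.degree)
        logger.info("GCV chose alpha=%.2f", alpha)
    else:
        alpha = float(config.alpha)
    resolved = dataclasses.replace(resolved, alpha=alpha)
    fit = loess_fit(y_target, X.times, alpha, config.degree)
    _write_tsv(
        pd.DataFrame(
            {
                "time": X.times,
                "observed": y_target,
                "fitted": fit.fitted,
                "residual": fit.residuals,
            }
        ),
        out("smooth.tsv"),
    )

    # -- distances ----------------------------------------------------------
    params = (
        {"weighting": config.dtw_weighting}
        if config.metric == "dtw"
        else {"n": config.minkowski_n}
    )
    table = compute_target_distances(X, fit, config.metric, params)
    ranks = global_ranks(table)
    _write_tsv(
        pd.DataFrame(
            {"gene_id": table.gene_ids, "distance": table.distances, "rank": ranks}
        ),
        out("distances.tsv"),
    )

    # -- selection ----------------------------------------------------------
    sel = select_genes(
        table, labels, cluster_index,
        start=config.start, step=config.step, threshold=config.p_threshold,
    )
    logger.info(
        "%d significant genes, %d rescued from other clusters",
        sel.n_sig, len(sel.rescued_ids),
    )
    id_to_idx = {g: i for i, g in enumerate(table.gene_ids)}
    rows = [
        (g, table.distances[id_to_idx[g]], ranks[id_to_idx[g]], status)
        for status, ids in (("significant", sel.significant_ids),
                            ("rescued", sel.rescued_ids))
        for g in ids
    ]
    _write_tsv(
        pd.DataFrame(rows, columns=["gene_id", "distance", "global_rank", "status"]),
        out("selection.tsv"),
    )
    _write_tsv(
        pd.DataFrame(sel.p_trace, columns=["n", "p"]), out("p_trace.tsv")
    )

    # -- network ------------------------------------------------------------
    panel_ids = list(
        dict.fromkeys(
            list(sel.significant_ids) + list(sel.rescued_ids) + [config.target]
        )
    )
    X_sel = X.subset(panel_ids)
    logger.info("network stage on %d genes", X_sel.n_genes)
    var_model = fit_var1(X_sel)
    _write_tsv(
        pd.DataFrame(var_model.A, columns=panel_ids).assign(gene_id=panel_ids)[
            ["gene_id"] + panel_ids
        ],
        out("A-matrix.tsv"),
    )
    edge_frames = []
    results: dict = {
        "matrix": X,
        "cluster_model": model,
        "cluster_index": cluster_index,
        "smooth": fit,
        "distances": table,
        "selection": sel,
        "var_model": var_model,
        "panel_ids": panel_ids,
    }
    if config.mode in ("var", "both"):
        P = lagged_partial_correlation_matrix(X_sel)
        lagged = top_edges(P, panel_ids, n_top=config.top_n_edges, directed=True)
        edge_frames.append(
            pd.DataFrame(lagged.to_records()).assign(type="lagged")
        )
        results["lagged_edges"] = lagged
    if config.mode in ("dynamic", "both"):
        corr = dynamic_correlation_matrix(X_sel)
        pcor = dynamic_partial_correlation(corr, shrinkage=config.dynamic_shrinkage)
        dyn = top_edges(pcor, panel_ids, n_top=config.top_n_edges, directed=False)
        edge_frames.append(pd.DataFrame(dyn.to_records()).assign(type="dynamic"))
        results["dynamic_edges"] = dyn
    if not edge_frames:
        raise ValueError(f"unknown network mode: {config.mode!r}")
    _write_tsv(pd.concat(edge_frames, ignore_index=True), out("edges.tsv"))

    with open(out("manifest.txt"), "w") as fh:
        fh.write(resolved.to_manifest())
    results["config"] = resolved
    return results
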