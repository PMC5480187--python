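"""Simulation benchmark: replicate datasets per parameter cell, four
candidate distances, connectivity-selected k, purity at the selected k.

For every cell of the (delta, rho, B, p_G, p_W) grid and every replicate a
fresh dataset is simulated, each requested distance is computed, the
number of clusters is selected by the connectivity criterion, the samples
are clustered at that k, and purity against the planted grouping is
recorded.  The headline aggregate is the success rate of selecting k = 3
(the true number of groups) and the median purity.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateScoreError
from .evaluate import EvalOptions, purity, select_k_connectivity
from .gmm import DownsampleOptions, GmmOptions, _seed_int, cluster_all_pathways
from .io import ExpressionMatrix, GeneSetCollection
from .score import euclidean_distance, final_distance, score_matrix
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "BenchmarkCell",
    "BenchmarkConfig",
    "BenchmarkReport",
    "run_benchmark",
    "METHODS",
]

METHODS = (
    "euclid_all",
    "euclid_pathway_genes",
    "pathway_score",
    "pathway_score_downsampled",
)


@dataclass(frozen=True)
class BenchmarkCell:
    """One simulation parameter setting."""

    delta: float
    rho: float = 0.0
    b: float = 1.0
    p_g: float = 0.8
    p_w: float = 0.2


@dataclass
class BenchmarkConfig:
    cells: list[BenchmarkCell]
    replicates: int = 10
    methods: tuple[str, ...] = ("euclid_all", "euclid_pathway_genes", "pathway_score")
    clustering_methods: tuple[str, ...] = ("kmeans", "hierarchical")
    eval_options: EvalOptions = field(default_factory=EvalOptions)
    gmm_options: GmmOptions = field(default_factory=GmmOptions)
    downsample_options: DownsampleOptions = field(default_factory=DownsampleOptions)
    group_sizes: tuple[int, ...] = (40, 40, 40)
    m_total: int = 22148
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.cells or not self.methods or not self.clustering_methods:
            raise ValueError("cells, methods and clustering_methods must be nonempty")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


@dataclass
class BenchmarkReport:
    """Per-replicate records plus per-cell aggregates.

    ``records`` has one row per cell x replicate x method x clustering
    method; ``summary`` aggregates success rate of selecting k = 3 and the
    purity distribution.  ``n_failures`` counts replicates excluded because
    a method degenerated (e.g. no voting pathway).
    """

    records: pd.DataFrame
    summary: pd.DataFrame
    n_failures: int = 0

    @staticmethod
    def summarize(records: pd.DataFrame) -> pd.DataFrame:
        grouped = records.groupby(
            ["delta", "rho", "b", "p_g", "p_w", "method", "clustering"],
            as_index=False,
        )
        summary = grouped.agg(
            n=("selected_k", "size"),
            success_rate=("selected_k", lambda s: float((s == 3).mean())),
            purity_median=("purity", "median"),
            purity_q25=("purity", lambda s: float(s.quantile(0.25))),
            purity_q75=("purity", lambda s: float(s.quantile(0.75))),
        )
        return summary


def _method_inputs(
    method: str,
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    gmm_opts: GmmOptions,
    ds_opts: DownsampleOptions,
):
    """Distance matrix and K-means feature matrix for one method."""
    if method == "euclid_all":
        dist = euclidean_distance(expr)
        features = expr.values.T
    elif method == "euclid_pathway_genes":
        dist = euclidean_distance(expr, sets)
        features = expr.submatrix(sets.all_genes())
    elif method in ("pathway_score", "pathway_score_downsampled"):
        downsample = ds_opts if method == "pathway_score_downsampled" else None
        clusterings = cluster_all_pathways(expr, sets, gmm_opts, downsample)
        score = score_matrix(clusterings, expr.sample_ids)
        dist = final_distance(score)
        features = score.values.T
    else:  # pragma: no cover - validated in BenchmarkConfig
        raise ValueError(f"unknown method {method!r}")
    return dist, features


def run_benchmark(config: BenchmarkConfig, sets: GeneSetCollection) -> BenchmarkReport:
    """Run the full grid.  Replicate seeds are derived from the master seed
    and the (cell, replicate) indices, so any single replicate can be
    re-run in isolation and cells are independent of execution order."""
    rows = []
    n_failures = 0
    for cell_idx, cell in enumerate(config.cells):
        for rep in range(config.replicates):
            sim_seed = _seed_int(config.seed, cell_idx, rep)
            sim_cfg = SimulationConfig(
                group_sizes=config.group_sizes,
                delta=cell.delta,
                p_w=cell.p_w,
                p_g=cell.p_g,
                rho=cell.rho,
                b=cell.b,
                m_total=config.m_total,
                seed=sim_seed,
            )
            dataset = simulate_dataset(sim_cfg, sets)
            expr, truth = dataset.expr, dataset.truth
            for m_idx, method in enumerate(config.methods):
                gmm_opts = config.gmm_options.replace(
                    seed=_seed_int(config.seed, cell_idx, rep, m_idx)
                )
                ds_opts = dataclasses.replace(
                    config.downsample_options,
                    seed=_seed_int(config.seed, cell_idx, rep, m_idx, 1),
                )
                try:
                    dist, features = _method_inputs(method, expr, sets, gmm_opts, ds_opts)
                except DegenerateScoreError as exc:
                    n_failures += 1
                    logger.warning(
                        "cell %s rep %d method %s degenerate: %s",
                        cell,
                        rep,
                        method,
                        exc,
                    )
                    continue
                for clustering in config.clustering_methods:
                    eval_opts = EvalOptions(
                        L=config.eval_options.L,
                        k_range=config.eval_options.k_range,
                        linkage=config.eval_options.linkage,
                        kmeans_n_init=config.eval_options.kmeans_n_init,
                        seed=_seed_int(config.seed, cell_idx, rep, m_idx, 2),
                    )
                    sel = select_k_connectivity(
                        dist, method=clustering, opts=eval_opts, features=features
                    )
                    rows.append(
                        {
                            "delta": cell.delta,
                            "rho": cell.rho,
                            "b": cell.b,
                            "p_g": cell.p_g,
                            "p_w": cell.p_w,
                            "replicate": rep,
                            "method": method,
                            "clustering": clustering,
                            "selected_k": sel.k,
                            "purity": purity(sel.partition, truth),
                            "connectivity_trace": ";".join(
                                f"{k}:{v:.6g}" for k, v in sorted(sel.trace.items())
                            ),
                        }
                    )
    records = pd.DataFrame(
        rows,
        columns=[
            "delta",
            "rho",
            "b",
            "p_g",
            "p_w",
            "replicate",
            "method",
            "clustering",
            "selected_k",
            "purity",
            "connectivity_trace",
        ],
    )
    summary = BenchmarkReport.summarize(records) if len(records) else pd.DataFrame()
    return BenchmarkReport(records, summary, n_failures)
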