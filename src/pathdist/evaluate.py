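"""Cluster-validation criteria and clustering wrappers.

Implements the connectivity criterion (sum of 1/j penalties for j-th
nearest neighbours falling outside a sample's cluster; minimised), the
Dunn index (min between-cluster / max within-cluster distance; maximised)
and purity (fraction of samples covered by their predicted cluster's
majority true label), together with K-means and average-linkage
hierarchical wrappers and connectivity-based selection of the number of
clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .errors import AlignmentError, ParameterError
from .io import DistanceMatrix

__all__ = [
    "Partition",
    "EvalOptions",
    "SelectKResult",
    "connectivity",
    "dunn_index",
    "purity",
    "kmeans_cluster",
    "hierarchical_cluster",
    "select_k_connectivity",
]


def relabel_first_appearance(raw: np.ndarray) -> np.ndarray:
    """Map arbitrary labels to consecutive integers 1..K in order of first
    appearance.  Drops empty labels by construction."""
    mapping: dict = {}
    out = np.empty(len(raw), dtype=int)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


@dataclass
class Partition:
    """A clustering of samples into K_C nonempty clusters labelled 1..K_C."""

    sample_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.sample_ids),):
            raise ParameterError("labels length must equal number of samples")
        present = np.unique(self.labels)
        if len(present) == 0 or present[0] < 1 or present[-1] != len(present):
            raise ParameterError(
                "labels must be 1..K with every cluster nonempty; "
                f"got values {present}"
            )

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class EvalOptions:
    """Options for validation criteria and the clustering wrappers.

    L
        neighbours per sample in the connectivity sum.
    k_range
        candidate numbers of clusters for optimal-k selection.
    linkage
        hierarchical linkage rule (single/complete/average).
    kmeans_n_init
        K-means restarts.
    """

    L: int = 10
    k_range: tuple[int, ...] = (2, 3, 4, 5)
    linkage: str = "average"
    kmeans_n_init: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ParameterError(f"L must be >= 1, got {self.L}")
        self.k_range = tuple(int(k) for k in self.k_range)
        if not self.k_range or min(self.k_range) < 2:
            raise ParameterError("k_range must be nonempty with min >= 2")
        if self.linkage not in ("single", "complete", "average"):
            raise ParameterError(f"unsupported linkage {self.linkage!r}")
        if self.kmeans_n_init < 1:
            raise ParameterError("kmeans_n_init must be >= 1")


def _check_alignment(partition: Partition, dist: DistanceMatrix) -> None:
    if partition.sample_ids != dist.sample_ids:
        raise AlignmentError("partition and distance matrix sample ids differ")


def neighbor_order(dist_values: np.ndarray) -> np.ndarray:
    """Per-row neighbour lists by increasing distance, self excluded.

    Ties are broken by ascending sample index so the result is deterministic
    on highly tied matrices (score matrices are multiples of one count).
    Returns an (N, N-1) index array.
    """
    n = dist_values.shape[0]
    out = np.empty((n, n - 1), dtype=int)
    idx = np.arange(n)
    for i in range(n):
        others = idx[idx != i]
        order = np.lexsort((others, dist_values[i, others]))
        out[i] = others[order]
    return out


def connectivity(partition: Partition, dist: DistanceMatrix, L: int) -> float:
    """Connectivity of a partition given a distance (lower is better).

    For each sample the L nearest other samples are found (ties broken by
    sample index); each j-th neighbour lying in a different cluster adds
    1/j.  Zero iff every sample's L nearest neighbours share its cluster.
    """
    _check_alignment(partition, dist)
    n = partition.n_samples
    if not 1 <= L <= n - 1:
        raise ParameterError(f"L must be in [1, {n - 1}], got {L}")
    nn = neighbor_order(dist.values)[:, :L]
    labels = partition.labels
    penalties = (labels[nn] != labels[:, None]) / np.arange(1, L + 1)[None, :]
    return float(penalties.sum())


def dunn_index(partition: Partition, dist: DistanceMatrix) -> float:
    """Dunn index: min between-cluster over max within-cluster distance.

    Higher is better.  Returns ``inf`` when every cluster is a singleton or
    all within-cluster distances are zero.
    """
    _check_alignment(partition, dist)
    if partition.n_clusters < 2:
        raise ParameterError("Dunn index requires at least 2 clusters")
    labels = partition.labels
    same = labels[:, None] == labels[None, :]
    off_diag = ~np.eye(len(labels), dtype=bool)
    within = dist.values[same & off_diag]
    between = dist.values[~same]
    max_within = within.max() if within.size else 0.0
    min_between = between.min()
    if max_within == 0.0:
        return float("inf")
    return float(min_between / max_within)


def purity(partition: Partition, truth: Partition) -> float:
    """Fraction of samples whose predicted cluster's majority true label
    matches their own; 1 iff every predicted cluster is pure."""
    if partition.sample_ids != truth.sample_ids:
        raise AlignmentError("partition and truth sample ids differ")
    n = partition.n_samples
    table = np.zeros((partition.n_clusters, truth.n_clusters), dtype=int)
    np.add.at(table, (partition.labels - 1, truth.labels - 1), 1)
    return float(table.max(axis=1).sum() / n)


def kmeans_cluster(
    data: np.ndarray, sample_ids: list[str], k: int, opts: EvalOptions
) -> Partition:
    """Best-of-``kmeans_n_init`` K-means on a samples-by-features matrix."""
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if k > n:
        raise ParameterError(f"k={k} exceeds number of samples {n}")
    km = KMeans(
        n_clusters=k,
        n_init=opts.kmeans_n_init,
        random_state=opts.seed,
    ).fit(data)
    return Partition(sample_ids, relabel_first_appearance(km.labels_))


def hierarchical_cluster(
    dist: DistanceMatrix, k: int, linkage: str = "average"
) -> Partition:
    """Agglomerative clustering on a precomputed distance, cut at k."""
    n = dist.n_samples
    if k > n:
        raise ParameterError(f"k={k} exceeds number of samples {n}")
    if k == 1:
        return Partition(dist.sample_ids, np.ones(n, dtype=int))
    Z = scipy_linkage(squareform(dist.values, checks=False), method=linkage)
    raw = fcluster(Z, t=k, criterion="maxclust")
    return Partition(dist.sample_ids, relabel_first_appearance(raw))


@dataclass
class SelectKResult:
    """Outcome of connectivity-based selection of the number of clusters."""

    k: int
    trace: dict[int, float]
    dunn_trace: dict[int, float] = field(default_factory=dict)
    partitions: dict[int, Partition] = field(default_factory=dict)

    @property
    def partition(self) -> Partition:
        return self.partitions[self.k]


def select_k_connectivity(
    dist: DistanceMatrix,
    method: str,
    opts: EvalOptions,
    features: np.ndarray | None = None,
) -> SelectKResult:
    """Choose the number of clusters minimising connectivity.

    For each k in ``opts.k_range`` a partition is produced by ``method``
    ('kmeans' on ``features``, one row per sample; or 'hierarchical' on
    ``dist``), its connectivity against ``dist`` is computed, and the
    argmin is returned.  Exact ties are broken toward the LARGER k:
    connectivity penalises splitting a tight neighbourhood but is blind to
    merging well-separated clusters (any coarsening of a
    neighbourhood-closed partition also scores zero), so among tied minima
    the finest partition is the informative one.  The Dunn index is
    recorded alongside for reporting.
    """
    if method not in ("kmeans", "hierarchical"):
        raise ParameterError(f"unknown clustering method {method!r}")
    if method == "kmeans" and features is None:
        raise ParameterError("kmeans selection requires a feature matrix")
    n = dist.n_samples
    if max(opts.k_range) > n - 1:
        raise ParameterError("k_range must lie within 2..N-1")
    trace: dict[int, float] = {}
    dunn_trace: dict[int, float] = {}
    partitions: dict[int, Partition] = {}
    best_k, best_conn = None, np.inf
    for k in sorted(opts.k_range):
        if method == "kmeans":
            part = kmeans_cluster(features, dist.sample_ids, k, opts)
        else:
            part = hierarchical_cluster(dist, k, opts.linkage)
        conn = connectivity(part, dist, opts.L)
        trace[k] = conn
        dunn_trace[k] = (
            dunn_index(part, dist) if part.n_clusters >= 2 else float("nan")
        )
        partitions[k] = part
        if conn <= best_conn:
            best_k, best_conn = k, conn
    return SelectKResult(best_k, trace, dunn_trace, partitions)
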