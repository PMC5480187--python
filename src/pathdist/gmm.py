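"""Per-pathway clustering with BIC-selected Gaussian mixture models.

Each pathway's member-gene submatrix (samples x genes) is clustered with a
full-covariance multivariate Gaussian mixture fitted by EM; the number of
components is chosen by maximising BIC = 2*logL - df*log(n) with
df = (k-1) + k*p + k*p*(p+1)/2.  For k = 1 this df is (p^2+3p)/2, the
parameter count of a single p-variate Gaussian.  Large pathways are
handled by the downsampling procedure: many small random gene subsets are
clustered independently and their votes are combined into a subset-level
disagreement distance from which the pathway's single partition is drawn.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .errors import DataError, ShapeError
from .evaluate import EvalOptions, relabel_first_appearance, select_k_connectivity
from .io import DistanceMatrix, ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "GmmOptions",
    "DownsampleOptions",
    "PathwayClustering",
    "gmm_bic_df",
    "fit_gmm_select_k",
    "downsample_cluster_pathway",
    "cluster_all_pathways",
    "clusterings_to_table",
]


#: covariance families searched by default, simplest first (tie-break order)
DEFAULT_FAMILIES = ("spherical", "diag", "tied", "full")


@dataclass
class GmmOptions:
    """EM fitting and model-selection options.

    k_max
        largest candidate component count (candidates are 1..k_max).
    covariance_families
        covariance structures searched jointly with k, as in model-based
        clustering practice: 'spherical' (one variance per component),
        'diag', 'tied' (one shared full covariance) and 'full'
        (unconstrained per-component).  With ~100 samples a full p x p
        covariance per component costs k*p(p+1)/2 parameters and BIC can
        never justify k > 1 even for well-separated groups, so restricting
        the search to ('full',) largely disables the method; the
        constrained families keep it usable exactly where a mixture
        package's default family search would.
    reg_covar
        ridge added to covariance diagonals for numerical stability.
    n_init
        EM restarts per candidate (best log-likelihood kept).
    """

    k_max: int = 5
    covariance_families: tuple[str, ...] = DEFAULT_FAMILIES
    reg_covar: float = 1e-6
    n_init: int = 5
    max_iter: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_max < 1:
            raise ShapeError(f"k_max must be >= 1, got {self.k_max}")
        if isinstance(self.covariance_families, str):
            self.covariance_families = (self.covariance_families,)
        unknown = set(self.covariance_families) - set(DEFAULT_FAMILIES)
        if unknown or not self.covariance_families:
            raise ShapeError(f"unknown covariance families: {sorted(unknown)}")
        if self.reg_covar <= 0:
            raise ShapeError("reg_covar must be > 0")
        if self.n_init < 1:
            raise ShapeError("n_init must be >= 1")

    def replace(self, **kwargs) -> "GmmOptions":
        from dataclasses import replace as dc_replace

        return dc_replace(self, **kwargs)


@dataclass
class DownsampleOptions:
    """Options for the large-pathway downsampling procedure.

    Pathways with more than ``trigger_size`` matched genes are clustered by
    drawing ``n_subsets`` random subsets of ``subset_size`` genes, clustering
    each subset with the BIC-selected mixture, and voting.
    """

    subset_size: int = 10
    n_subsets: int = 100
    trigger_size: int = 10
    k_range: tuple[int, ...] = (2, 3, 4, 5)
    L: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.subset_size <= self.trigger_size:
            raise ShapeError("need 2 <= subset_size <= trigger_size")
        if self.n_subsets < 1:
            raise ShapeError("n_subsets must be >= 1")


@dataclass
class PathwayClustering:
    """One pathway's sample partition.

    ``labels`` are consecutive integers 1..m_k (order of first appearance);
    ``m_k`` is the selected number of clusters.  ``bic_trace`` maps each
    successfully fitted candidate k to its BIC (empty for downsampled
    pathways, whose k is chosen by connectivity instead).
    """

    pathway_name: str
    labels: np.ndarray
    m_k: int
    n_genes_used: int
    method: str = "gmm"
    bic_trace: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = np.unique(self.labels)
        if self.m_k != len(present) or present[0] != 1 or present[-1] != self.m_k:
            raise ShapeError(
                f"labels must be consecutive 1..m_k={self.m_k}, got {present}"
            )


def gmm_bic_df(k: int, p: int, family: str = "full") -> int:
    """Free-parameter count of a k-component p-variate mixture:
    (k-1) weights + k*p means + the family's covariance parameters.
    For family='full' and k=1 this is (p^2 + 3p)/2."""
    cov_params = {
        "spherical": k,
        "diag": k * p,
        "tied": p * (p + 1) // 2,
        "full": k * p * (p + 1) // 2,
    }[family]
    return (k - 1) + k * p + cov_params


def _seed_int(*entropy: int) -> int:
    """Deterministic 31-bit seed derived from a tuple of integers."""
    return int(np.random.SeedSequence(list(entropy)).generate_state(1)[0] % (2**31))


def _fit_is_degenerate(gm, data: np.ndarray, reg_covar: float) -> bool:
    """Detect likelihood spikes: a component collapsed onto a few samples.

    The mixture likelihood is unbounded when a component's covariance
    shrinks toward the ridge floor, which produces spurious BIC winners
    (most often for the unconstrained family when a component holds barely
    more samples than dimensions).  A fit is rejected when any component
    holds fewer than 2 expected samples or any covariance eigenvalue sits
    at the regularisation floor relative to the data scale.
    """
    n = data.shape[0]
    if (gm.weights_ * n).min() < 2.0:
        return True
    cov = gm.covariances_
    if gm.covariance_type == "spherical":
        min_eig = cov.min()
    elif gm.covariance_type == "diag":
        min_eig = cov.min()
    elif gm.covariance_type == "tied":
        min_eig = np.linalg.eigvalsh(cov)[0]
    else:  # full
        min_eig = min(np.linalg.eigvalsh(c)[0] for c in cov)
    floor = max(10.0 * reg_covar, 1e-4 * float(data.var(axis=0).mean()))
    return min_eig < floor


def fit_gmm_select_k(
    data: np.ndarray,
    options: GmmOptions | None = None,
    pathway_name: str = "",
    sample_ids: list[str] | None = None,
) -> PathwayClustering:
    """Fit mixtures over k = 1..k_max and the covariance families, keep the
    BIC-maximising model.

    ``data`` is samples x genes.  BIC is 2*logL - df*log(n), maximised; on
    ties the smaller k wins, then the simpler family (options order).
    Candidate fits that error out or fail to converge are skipped; if
    nothing beats the trivial model the result is a single cluster.
    Components left empty by the maximum-posterior assignment are dropped,
    so ``m_k`` always equals the number of distinct labels.  ``bic_trace``
    records, per k, the best BIC across the searched families.
    """
    options = options or GmmOptions()
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    if not np.all(np.isfinite(data)):
        raise DataError("GMM input contains non-finite values")
    n, p = data.shape
    if n < 2:
        raise ShapeError(f"need at least 2 samples, got {n}")

    bic_trace: dict[int, float] = {}
    best_k, best_bic, best_labels = None, -np.inf, None
    for k in range(1, options.k_max + 1):
        for family in options.covariance_families:
            try:
                gm = GaussianMixture(
                    n_components=k,
                    covariance_type=family,
                    reg_covar=options.reg_covar,
                    # k=1 EM is the closed-form single-Gaussian MLE;
                    # restarts would refit the identical model.
                    n_init=1 if k == 1 else options.n_init,
                    max_iter=options.max_iter,
                    random_state=_seed_int(options.seed, k),
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    gm.fit(data)
                if not gm.converged_:
                    logger.debug(
                        "%s: k=%d %s did not converge, skipped",
                        pathway_name, k, family,
                    )
                    continue
                if k > 1 and _fit_is_degenerate(gm, data, options.reg_covar):
                    logger.debug(
                        "%s: k=%d %s degenerate (collapsed component), skipped",
                        pathway_name, k, family,
                    )
                    continue
                log_l = float(gm.score(data)) * n
            except Exception as exc:  # singular fit etc. -- skip
                logger.debug(
                    "%s: k=%d %s fit failed (%s), skipped",
                    pathway_name, k, family, exc,
                )
                continue
            bic = 2.0 * log_l - gmm_bic_df(k, p, family) * np.log(n)
            if k not in bic_trace or bic > bic_trace[k]:
                bic_trace[k] = bic
            if bic > best_bic:
                best_k, best_bic = k, bic
                best_labels = gm.predict(data)

    if best_k is None:
        # even the single-Gaussian fit failed; degrade to one cluster
        labels = np.ones(n, dtype=int)
    else:
        labels = relabel_first_appearance(best_labels)
    return PathwayClustering(
        pathway_name=pathway_name,
        labels=labels,
        m_k=int(labels.max()),
        n_genes_used=p,
        method="gmm",
        bic_trace=bic_trace,
    )


def downsample_cluster_pathway(
    expr_subset: np.ndarray,
    opts: DownsampleOptions,
    gmm: GmmOptions,
    pathway_name: str = "",
    sample_ids: list[str] | None = None,
) -> PathwayClustering:
    """Cluster a large pathway through random small gene subsets.

    Draws ``n_subsets`` subsets of ``subset_size`` genes without replacement
    (within a subset), clusters each with the BIC-selected mixture, and
    forms the subset-vote distance: for a sample pair, the proportion of
    multi-cluster subsets that separate the pair.  The number of clusters
    for the pathway is then chosen in ``k_range`` by minimising the
    connectivity of K-means partitions of the vote matrix (columns as
    feature vectors), and the K-means partition at that k is returned.

    Identical subsets receive identical fitting seeds, so at the boundary
    s_k = subset_size the procedure reduces to the direct mixture fit.
    """
    data = np.asarray(expr_subset, dtype=float)
    n, s_k = data.shape
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(n)]
    if s_k < opts.subset_size:
        logger.warning(
            "%s: %d genes < subset_size %d; falling back to direct GMM",
            pathway_name,
            s_k,
            opts.subset_size,
        )
        return fit_gmm_select_k(data, gmm, pathway_name)

    rng = np.random.default_rng(opts.seed)
    disagree = np.zeros((n, n))
    n_voting = 0
    for _ in range(opts.n_subsets):
        idx = np.sort(rng.choice(s_k, size=opts.subset_size, replace=False))
        # seed keyed by subset membership: duplicate subsets refit identically
        sub_opts = gmm.replace(seed=_seed_int(gmm.seed, zlib.crc32(idx.tobytes())))
        result = fit_gmm_select_k(data[:, idx], sub_opts, pathway_name)
        if result.m_k > 1:
            disagree += result.labels[:, None] != result.labels[None, :]
            n_voting += 1

    if n_voting == 0:
        return PathwayClustering(
            pathway_name=pathway_name,
            labels=np.ones(n, dtype=int),
            m_k=1,
            n_genes_used=s_k,
            method="downsampled",
        )

    votes = disagree / n_voting
    vote_dist = DistanceMatrix(sample_ids, votes)
    eval_opts = EvalOptions(
        L=min(opts.L, n - 1),
        k_range=tuple(k for k in opts.k_range if k <= n - 1),
        seed=_seed_int(opts.seed, 1),
    )
    selection = select_k_connectivity(
        vote_dist, method="kmeans", opts=eval_opts, features=votes
    )
    labels = relabel_first_appearance(selection.partition.labels)
    return PathwayClustering(
        pathway_name=pathway_name,
        labels=labels,
        m_k=int(labels.max()),
        n_genes_used=s_k,
        method="downsampled",
    )


def cluster_all_pathways(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    options: GmmOptions | None = None,
    downsample: DownsampleOptions | None = None,
) -> list[PathwayClustering]:
    """Cluster the samples once per pathway, in collection order.

    ``sets`` must already be matched to ``expr`` (every member gene
    measured).  Pathways larger than ``downsample.trigger_size`` use the
    downsampling procedure when ``downsample`` is given; all others are fit
    directly.  Per-pathway seeds are derived from the master seed and the
    pathway index, so runs are reproducible and pathway-order stable.  A
    pathway whose fit fails outright is recorded as a single cluster rather
    than aborting the run.
    """
    options = options or GmmOptions()
    results: list[PathwayClustering] = []
    for idx, (name, genes) in enumerate(sets):
        data = expr.submatrix(genes)
        pw_gmm = options.replace(seed=_seed_int(options.seed, idx))
        try:
            if downsample is not None and len(genes) > downsample.trigger_size:
                pw_ds = DownsampleOptions(
                    subset_size=downsample.subset_size,
                    n_subsets=downsample.n_subsets,
                    trigger_size=downsample.trigger_size,
                    k_range=downsample.k_range,
                    L=downsample.L,
                    seed=_seed_int(downsample.seed, idx),
                )
                result = downsample_cluster_pathway(
                    data, pw_ds, pw_gmm, name, expr.sample_ids
                )
            else:
                result = fit_gmm_select_k(data, pw_gmm, name, expr.sample_ids)
        except Exception as exc:
            logger.warning("pathway %s failed (%s); recorded as one cluster", name, exc)
            result = PathwayClustering(
                pathway_name=name,
                labels=np.ones(expr.n_samples, dtype=int),
                m_k=1,
                n_genes_used=len(genes),
                method="gmm",
            )
        results.append(result)
    return results


def clusterings_to_table(clusterings: list[PathwayClustering], sample_ids: list[str]):
    """Long-format table: pathway, sample_id, label, m_k, method."""
    import pandas as pd

    rows = []
    for pc in clusterings:
        for sid, lab in zip(sample_ids, pc.labels):
            rows.append(
                {
                    "pathway": pc.pathway_name,
                    "sample_id": sid,
                    "label": int(lab),
                    "m_k": pc.m_k,
                    "method": pc.method,
                }
            )
    return pd.DataFrame(rows, columns=["pathway", "sample_id", "label", "m_k", "method"])
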