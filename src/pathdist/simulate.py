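"""Synthetic gene-expression datasets with planted group structure.

Samples fall into three groups (default 40/40/40).  A fraction p_W of the
pathways is chosen to carry the grouping; within each chosen pathway a
fraction p_G of the member genes is differentially expressed with group
means (-delta, 0, +delta).  Within a group, differential genes have unit
variance and pairwise covariance rho with every gene of the same pathway;
pooling the three equal groups then gives the marginal variance

    sigma^2 = 1 + 2*delta^2 / 3

for each differential gene.  All other genes have mean 0 and marginal
variance B*sigma^2, so B >= 1 scales the background noise floor.
Non-differential genes share the equicovariance rho within their pathway
block; genes assigned to no pathway ("filler", up to ``m_total`` measured
genes) are mutually independent.  Pathway blocks are independent of each
other.

Each pathway block with covariance rho*J + diag(v_g - rho) is sampled
exactly through a shared standard-normal factor:

    g = mu + sqrt(rho) * z_block + sqrt(v_g - rho) * eps_g,

which is positive definite whenever rho < 1 <= v_g; this is verified and a
configuration error is raised otherwise (it cannot occur for rho in [0, 1)
and B >= 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ShapeError
from .evaluate import Partition
from .io import ExpressionMatrix, GeneSetCollection

__all__ = [
    "SimulationConfig",
    "LabeledDataset",
    "generate_synthetic_genesets",
    "simulate_dataset",
    "empirical_moment_check",
    "round_half_up",
]


def round_half_up(x: float) -> int:
    """round() with .5 always going up, fixed for reproducible counts
    (20% of 186 pathways -> 37)."""
    return int(math.floor(x + 0.5))


@dataclass
class SimulationConfig:
    """Parameters of the block-covariance simulation model.

    group_sizes
        samples per group; three groups with means -delta, 0, +delta.
    delta
        group mean shift of differential genes.
    p_w, p_g
        fraction of pathways chosen, and of member genes chosen per
        chosen pathway.
    rho
        within-pathway pairwise covariance (within-group).
    b
        background variance factor; non-differential genes have marginal
        variance B*sigma^2.
    m_total
        total measured genes; genes beyond the pathway union are
        independent filler (default 22148, an expression-array-sized
        transcriptome).
    """

    group_sizes: tuple[int, ...] = (40, 40, 40)
    delta: float = 1.0
    p_w: float = 0.2
    p_g: float = 0.8
    rho: float = 0.0
    b: float = 1.0
    m_total: int = 22148
    seed: int = 0

    def __post_init__(self) -> None:
        self.group_sizes = tuple(int(g) for g in self.group_sizes)
        if len(self.group_sizes) != 3 or any(g < 1 for g in self.group_sizes):
            raise ConfigurationError("need three groups with at least 1 sample each")
        if not 0 < self.p_w <= 1 or not 0 < self.p_g <= 1:
            raise ConfigurationError("p_w and p_g must lie in (0, 1]")
        if not 0 <= self.rho < 1:
            raise ConfigurationError("rho must lie in [0, 1)")
        if self.delta < 0:
            raise ConfigurationError("delta must be >= 0")
        if self.b < 1:
            raise ConfigurationError("B must be >= 1")

    @property
    def sigma2(self) -> float:
        """Pooled marginal variance of a differential gene: 1 + 2*delta^2/3."""
        return 1.0 + 2.0 * self.delta**2 / 3.0

    @property
    def n_samples(self) -> int:
        return sum(self.group_sizes)


@dataclass
class LabeledDataset:
    """A simulated expression matrix plus its generating ground truth."""

    expr: ExpressionMatrix
    truth: Partition
    chosen_pathways: list[str]
    chosen_genes: dict[str, list[str]]
    config: SimulationConfig
    gene_roles: pd.DataFrame = field(repr=False, default=None)


def generate_synthetic_genesets(
    n_pathways: int, set_size: int, prefix: str = "SYNPW"
) -> GeneSetCollection:
    """Equally sized, non-overlapping synthetic pathways with deterministic
    names (``{prefix}{i}`` containing genes ``{prefix}{i}_G{j}``)."""
    if n_pathways < 1 or set_size < 1:
        raise ShapeError("n_pathways and set_size must be >= 1")
    sets = {
        f"{prefix}{i + 1}": [f"{prefix}{i + 1}_G{j + 1}" for j in range(set_size)]
        for i in range(n_pathways)
    }
    return GeneSetCollection(sets)


def _ownership(sets: GeneSetCollection) -> dict[str, str]:
    """First pathway (collection order) containing each gene.

    A gene shared by several pathways must have exactly one generating
    law; its block membership follows its owner, while every pathway
    containing it still sees its simulated values.
    """
    owner: dict[str, str] = {}
    for name, genes in sets:
        for g in genes:
            owner.setdefault(g, name)
    return owner


def simulate_dataset(
    config: SimulationConfig, sets: GeneSetCollection
) -> LabeledDataset:
    """Draw one labelled dataset from the block-covariance model."""
    if len(sets) == 0:
        raise ConfigurationError("gene-set collection is empty")
    rng = np.random.default_rng(config.seed)
    names = sets.names
    K = len(names)

    n_chosen = max(1, round_half_up(config.p_w * K))
    chosen_idx = np.sort(rng.choice(K, size=n_chosen, replace=False))
    chosen_pathways = [names[i] for i in chosen_idx]
    chosen_set = set(chosen_pathways)

    owner = _ownership(sets)
    chosen_genes: dict[str, list[str]] = {}
    differential: set[str] = set()
    for name in chosen_pathways:
        members = sets.sets[name]
        n_g = max(1, round_half_up(config.p_g * len(members)))
        picked = [members[i] for i in np.sort(rng.choice(len(members), n_g, replace=False))]
        chosen_genes[name] = picked
        # a gene owned by an earlier pathway keeps that pathway's law
        differential.update(g for g in picked if owner[g] == name)

    pathway_genes = list(owner)  # first-occurrence order over the collection
    n_filler = max(0, config.m_total - len(pathway_genes))
    filler = [f"FILLER{i + 1}" for i in range(n_filler)]
    gene_ids = pathway_genes + filler
    M = len(gene_ids)
    N = config.n_samples

    sigma2 = config.sigma2
    bg_var = config.b * sigma2
    if not (config.rho < 1.0 and config.rho < bg_var):
        raise ConfigurationError(
            f"pathway block covariance not positive definite: rho={config.rho}, "
            f"variances (1, {bg_var})"
        )

    # per-gene marginal (within-group) variance and differential flag
    is_diff = np.array(
        [g in differential and owner[g] in chosen_set for g in pathway_genes]
        + [False] * n_filler
    )
    var = np.where(is_diff, 1.0, bg_var)

    # group means per gene
    g1, g2, g3 = config.group_sizes
    group_of_sample = np.repeat([1, 2, 3], [g1, g2, g3])
    mu_by_group = {1: -config.delta, 2: 0.0, 3: config.delta}
    mean = np.zeros((M, N))
    for grp, mu in mu_by_group.items():
        cols = group_of_sample == grp
        mean[np.ix_(is_diff, cols)] = mu

    block_of_gene = np.full(M, -1, dtype=int)
    name_to_block = {name: i for i, name in enumerate(names)}
    for gi, g in enumerate(pathway_genes):
        block_of_gene[gi] = name_to_block[owner[g]]

    eps = rng.standard_normal((M, N))
    if config.rho > 0:
        z = rng.standard_normal((K, N))
        in_block = block_of_gene >= 0
        shared = np.zeros((M, N))
        shared[in_block] = z[block_of_gene[in_block]]
        # filler genes carry no shared factor: full variance stays in eps
        resid_var = var - np.where(in_block, config.rho, 0.0)
        values = mean + math.sqrt(config.rho) * shared + np.sqrt(resid_var)[:, None] * eps
    else:
        values = mean + np.sqrt(var)[:, None] * eps

    sample_ids = [f"S{j + 1}" for j in range(N)]
    expr = ExpressionMatrix(gene_ids, sample_ids, values)
    truth = Partition(sample_ids, group_of_sample)
    roles = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "owner_pathway": [owner.get(g, "") for g in pathway_genes]
            + [""] * n_filler,
            "differential": is_diff,
        }
    )
    return LabeledDataset(expr, truth, chosen_pathways, chosen_genes, config, roles)


def empirical_moment_check(dataset: LabeledDataset) -> dict:
    """Empirical moments of a simulated dataset against configured values.

    Reports per-group means of differential genes, pooled variances (target
    sigma^2 = 1 + 2*delta^2/3), background variances (target B*sigma^2) and
    within-group correlations of same-pathway differential gene pairs
    (target rho), each with a z-score against its Monte-Carlo standard
    error.
    """
    cfg = dataset.config
    expr = dataset.expr
    roles = dataset.gene_roles
    is_diff = roles["differential"].to_numpy()
    values = expr.values
    N = expr.n_samples
    g1, g2, g3 = cfg.group_sizes
    groups = [slice(0, g1), slice(g1, g1 + g2), slice(g1 + g2, N)]

    report: dict = {"config": cfg}
    diff_vals = values[is_diff]
    if diff_vals.size:
        report["group_means"] = [float(diff_vals[:, s].mean()) for s in groups]
        report["expected_group_means"] = [-cfg.delta, 0.0, cfg.delta]
        pooled_var = diff_vals.var(axis=1, ddof=1)
        report["pooled_var_mean"] = float(pooled_var.mean())
        report["pooled_var"] = pooled_var
        report["expected_pooled_var"] = cfg.sigma2

    bg = values[~is_diff][:200]  # a slice is enough for a moment check
    report["background_var_mean"] = float(bg.var(axis=1, ddof=1).mean())
    report["expected_background_var"] = cfg.b * cfg.sigma2

    # within-group correlation of same-pathway differential gene pairs
    corrs = []
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    for name in dataset.chosen_pathways:
        idx = [
            gene_index[g]
            for g in dataset.chosen_genes[name]
            if is_diff[gene_index[g]]
        ]
        if len(idx) < 2:
            continue
        for s in groups:
            block = values[np.ix_(idx, range(*s.indices(N)))]
            c = np.corrcoef(block)
            iu = np.triu_indices(len(idx), 1)
            corrs.extend(c[iu].tolist())
    if corrs:
        report["within_group_corr_mean"] = float(np.mean(corrs))
        report["within_group_corrs"] = np.asarray(corrs)
        report["expected_corr"] = cfg.rho
    return report
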