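"""The pathway-based distance score and its comparator distances.

For a sample pair (j1, j2) the score is

    d(j1, j2) = #{k : c_j1^k != c_j2^k, m_k > 1} / #{k : m_k > 1},

the proportion of multi-cluster ("voting") pathways whose partitions
separate the pair.  Pathways that found a single cluster carry no
information and are excluded from both numerator and denominator.  The
score matrix is then treated as a data matrix with one column per subject
and re-embedded: the final distance between two subjects is the Euclidean
distance between their columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import ConfigurationError, DegenerateScoreError, ShapeError
from .gmm import PathwayClustering
from .io import DistanceMatrix, ExpressionMatrix, GeneSetCollection

__all__ = ["ScoreMatrix", "score_matrix", "final_distance", "euclidean_distance"]


@dataclass
class ScoreMatrix:
    """N x N disagreement proportions over the voting pathways.

    Every entry times ``n_voting_pathways`` is an integer count of
    disagreeing pathways.
    """

    sample_ids: list[str]
    values: np.ndarray
    n_voting_pathways: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ShapeError(f"score matrix shape {self.values.shape} != ({n}, {n})")
        if self.n_voting_pathways < 1:
            raise ShapeError("n_voting_pathways must be >= 1")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ShapeError("score entries must lie in [0, 1]")
        if not np.array_equal(self.values, self.values.T) or np.any(
            np.diag(self.values) != 0
        ):
            raise ShapeError("score matrix must be symmetric with zero diagonal")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def as_distance(self) -> DistanceMatrix:
        return DistanceMatrix(self.sample_ids, self.values)


def score_matrix(
    clusterings: list[PathwayClustering],
    sample_ids: list[str] | None = None,
) -> ScoreMatrix:
    """Combine per-pathway partitions into the disagreement-proportion score.

    Raises :class:`DegenerateScoreError` when no pathway identified more
    than one cluster (the score would be identically zero); the error
    carries the zero matrix.
    """
    if not clusterings:
        raise ShapeError("no pathway clusterings given")
    n = len(clusterings[0].labels)
    for pc in clusterings:
        if len(pc.labels) != n:
            raise ShapeError(
                f"pathway {pc.pathway_name!r} has {len(pc.labels)} labels, expected {n}"
            )
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(n)]
    voting = [pc for pc in clusterings if pc.m_k > 1]
    if not voting:
        raise DegenerateScoreError(
            "no pathway identified more than one cluster; "
            "all pairwise distance scores are 0",
            zero_matrix=np.zeros((n, n)),
        )
    counts = np.zeros((n, n))
    for pc in voting:
        counts += pc.labels[:, None] != pc.labels[None, :]
    return ScoreMatrix(sample_ids, counts / len(voting), len(voting))


def final_distance(score: ScoreMatrix) -> DistanceMatrix:
    """Euclidean re-embedding of the score matrix.

    Each subject's column (including its diagonal zero) is treated as a
    coordinate vector; the final distance is the pairwise Euclidean norm
    between columns.  Being a Euclidean embedding it satisfies the triangle
    inequality, which the raw score need not.
    """
    cols = score.values.T  # one row per subject = that subject's column
    return DistanceMatrix(score.sample_ids, squareform(pdist(cols, "euclidean")))


def euclidean_distance(
    expr: ExpressionMatrix,
    gene_filter: GeneSetCollection | None = None,
) -> DistanceMatrix:
    """Pairwise Euclidean distance between samples.

    With no filter all M genes contribute; with a gene-set filter the
    union of matched pathway genes is used, each gene counted once however
    many pathways contain it.
    """
    if gene_filter is None:
        data = expr.values.T
    else:
        measured = set(expr.gene_ids)
        union = [g for g in gene_filter.all_genes() if g in measured]
        if not union:
            raise ConfigurationError(
                "no gene of the filter collection is present in the expression matrix"
            )
        data = expr.submatrix(union)
    return DistanceMatrix(expr.sample_ids, squareform(pdist(data, "euclidean")))
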