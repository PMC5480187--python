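"""Validation criteria against brute-force oracles and hand-worked cases."""

import numpy as np
import pytest

from pathdist.errors import AlignmentError, ParameterError
from pathdist.evaluate import (
    EvalOptions,
    Partition,
    connectivity,
    dunn_index,
    hierarchical_cluster,
    kmeans_cluster,
    purity,
    select_k_connectivity,
)
from pathdist.io import DistanceMatrix

from conftest import random_distance, random_partition, sample_ids


def brute_connectivity(labels, dist, L):
    """Materialise full sorted neighbour lists and sum 1/j penalties."""
    n = len(labels)
    total = 0.0
    for i in range(n):
        order = sorted((d, j) for j, d in enumerate(dist[i]) if j != i)
        for rank, (_, j) in enumerate(order[:L], start=1):
            if labels[j] != labels[i]:
                total += 1.0 / rank
    return total


def brute_dunn(labels, dist):
    n = len(labels)
    between = [
        dist[i, j] for i in range(n) for j in range(n) if labels[i] != labels[j]
    ]
    within = [
        dist[i, j]
        for i in range(n)
        for j in range(n)
        if i != j and labels[i] == labels[j]
    ]
    denom = max(within) if within else 0.0
    return float("inf") if denom == 0 else min(between) / denom


def brute_purity(pred, truth):
    n = len(pred)
    total = 0
    for c in set(pred):
        members = [i for i in range(n) if pred[i] == c]
        counts = {}
        for i in members:
            counts[truth[i]] = counts.get(truth[i], 0) + 1
        total += max(counts.values())
    return total / n


class TestConnectivity:
    def test_single_cluster_is_zero(self, rng):
        dist = random_distance(rng, 8)
        part = Partition(dist.sample_ids, np.ones(8, dtype=int))
        assert connectivity(part, dist, L=3) == 0.0

    def test_hand_worked_four_samples(self):
        # pairwise distances chosen so each sample's nearest neighbour is
        # its partner under the {1,3},{2,4} pairing
        d = np.zeros((4, 4))
        pairs = {(0, 2): 1, (1, 3): 2, (0, 3): 4, (0, 1): 5, (1, 2): 6, (2, 3): 7}
        for (i, j), v in pairs.items():
            d[i, j] = d[j, i] = v
        dist = DistanceMatrix(sample_ids(4), d)
        good = Partition(dist.sample_ids, np.array([1, 2, 1, 2]))
        bad = Partition(dist.sample_ids, np.array([1, 1, 2, 2]))
        assert connectivity(good, dist, L=1) == 0.0
        assert connectivity(bad, dist, L=1) == 4.0

    def test_matches_brute_force(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 16))
            dist = random_distance(rng, n)
            part = random_partition(rng, n, int(rng.integers(2, 5)))
            L = int(rng.integers(1, n))
            assert connectivity(part, dist, L) == pytest.approx(
                brute_connectivity(part.labels, dist.values, L), abs=1e-12
            )

    def test_l_out_of_range(self, rng):
        dist = random_distance(rng, 5)
        part = random_partition(rng, 5, 2)
        with pytest.raises(ParameterError):
            connectivity(part, dist, L=5)


class TestDunn:
    def test_singleton_clusters_give_infinity(self):
        d = np.array([[0.0, 5.0], [5.0, 0.0]])
        dist = DistanceMatrix(sample_ids(2), d)
        part = Partition(dist.sample_ids, np.array([1, 2]))
        assert dunn_index(part, dist) == float("inf")

    def test_hand_worked(self):
        # clusters {a,b} (within 1) and {c,d} (within 2), min cross 4
        d = np.array(
            [
                [0, 1, 4, 5],
                [1, 0, 6, 5],
                [4, 6, 0, 2],
                [5, 5, 2, 0],
            ],
            dtype=float,
        )
        dist = DistanceMatrix(sample_ids(4), d)
        part = Partition(dist.sample_ids, np.array([1, 1, 2, 2]))
        assert dunn_index(part, dist) == pytest.approx(2.0)

    def test_matches_brute_force(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 13))
            dist = random_distance(rng, n)
            part = random_partition(rng, n, int(rng.integers(2, 4)))
            assert dunn_index(part, dist) == pytest.approx(
                brute_dunn(part.labels, dist.values), abs=1e-12
            )

    def test_requires_two_clusters(self, rng):
        dist = random_distance(rng, 4)
        part = Partition(dist.sample_ids, np.ones(4, dtype=int))
        with pytest.raises(ParameterError):
            dunn_index(part, dist)


class TestPurity:
    def test_perfect_up_to_relabelling(self, rng):
        truth = random_partition(rng, 12, 3)
        perm = {1: 3, 2: 1, 3: 2}
        relabeled = Partition(
            truth.sample_ids,
            np.array([perm[x] for x in truth.labels]),
        )
        # Partition normalises labels to first-appearance order, so rebuild
        assert purity(relabeled, truth) == 1.0

    def test_hand_worked(self):
        pred = Partition(sample_ids(5), np.array([1, 1, 1, 2, 2]))
        truth = Partition(sample_ids(5), np.array([1, 1, 2, 2, 3]))
        assert purity(pred, truth) == pytest.approx(0.6)

    def test_matches_brute_force(self, rng):
        for _ in range(30):
            n = 20
            pred = random_partition(rng, n, int(rng.integers(2, 6)))
            truth = random_partition(rng, n, int(rng.integers(2, 6)))
            assert purity(pred, truth) == pytest.approx(
                brute_purity(pred.labels, truth.labels), abs=1e-12
            )

    def test_one_iff_refinement(self, rng):
        for _ in range(20):
            n = 15
            pred = random_partition(rng, n, int(rng.integers(2, 6)))
            truth = random_partition(rng, n, int(rng.integers(2, 5)))
            refines = all(
                len({truth.labels[i] for i in range(n) if pred.labels[i] == c}) == 1
                for c in np.unique(pred.labels)
            )
            assert (purity(pred, truth) == 1.0) == refines

    def test_mismatched_samples(self, rng):
        pred = random_partition(rng, 5, 2)
        truth = Partition([f"X{i}" for i in range(5)], pred.labels.copy())
        with pytest.raises(AlignmentError):
            purity(pred, truth)


class TestClusteringWrappers:
    def test_kmeans_recovers_separated_blobs(self, rng):
        data = np.concatenate([rng.normal(0, 1, 30), rng.normal(50, 1, 30)])[:, None]
        part = kmeans_cluster(data, sample_ids(60), 2, EvalOptions(seed=0))
        assert len(set(part.labels[:30])) == 1
        assert len(set(part.labels[30:])) == 1
        assert part.labels[0] != part.labels[-1]

    def test_kmeans_k_equals_n(self, rng):
        data = rng.normal(size=(6, 3))
        part = kmeans_cluster(data, sample_ids(6), 6, EvalOptions(seed=0))
        assert part.n_clusters == 6

    def test_kmeans_duplicate_rows_share_labels(self, rng):
        row = rng.normal(size=3)
        data = np.vstack([row, row, rng.normal(10, 1, 3), rng.normal(10, 1, 3)])
        part = kmeans_cluster(data, sample_ids(4), 2, EvalOptions(seed=0))
        assert part.labels[0] == part.labels[1]

    def test_kmeans_k_too_large(self, rng):
        with pytest.raises(ParameterError):
            kmeans_cluster(rng.normal(size=(4, 2)), sample_ids(4), 5, EvalOptions())

    def test_hierarchical_chain_cut(self):
        # chain 1-2:1, 2-3:10, 3-4:1 -> {1,2},{3,4} at k=2 (average linkage)
        d = np.array(
            [
                [0, 1, 11, 12],
                [1, 0, 10, 11],
                [11, 10, 0, 1],
                [12, 11, 1, 0],
            ],
            dtype=float,
        )
        dist = DistanceMatrix(sample_ids(4), d)
        part = hierarchical_cluster(dist, 2, "average")
        assert list(part.labels) == [1, 1, 2, 2]

    def test_hierarchical_degenerate_cuts(self, rng):
        dist = random_distance(rng, 6)
        assert hierarchical_cluster(dist, 1).n_clusters == 1
        assert hierarchical_cluster(dist, 6).n_clusters == 6


class TestSelectK:
    def test_recovers_three_planted_groups(self, rng):
        centers = np.array([[0, 0], [20, 0], [0, 20]])
        data = np.vstack([rng.normal(c, 1.0, size=(15, 2)) for c in centers])
        from scipy.spatial.distance import pdist, squareform

        dist = DistanceMatrix(sample_ids(45), squareform(pdist(data)))
        for method in ("kmeans", "hierarchical"):
            sel = select_k_connectivity(
                dist, method, EvalOptions(L=5, seed=0), features=data
            )
            assert sel.k == 3

    def test_structureless_data_still_selects(self, rng):
        data = rng.normal(size=(20, 3))
        from scipy.spatial.distance import pdist, squareform

        dist = DistanceMatrix(sample_ids(20), squareform(pdist(data)))
        sel = select_k_connectivity(
            dist, "kmeans", EvalOptions(L=5, seed=0), features=data
        )
        assert sel.k in (2, 3, 4, 5)
        assert len(sel.trace) == 4

    def test_trace_covers_k_range(self, rng):
        data = rng.normal(size=(15, 2))
        from scipy.spatial.distance import pdist, squareform

        dist = DistanceMatrix(sample_ids(15), squareform(pdist(data)))
        opts = EvalOptions(L=4, k_range=(2, 3, 4), seed=0)
        sel = select_k_connectivity(dist, "hierarchical", opts)
        assert sorted(sel.trace) == [2, 3, 4]
        assert sorted(sel.dunn_trace) == [2, 3, 4]

    def test_deterministic_under_seed(self, rng):
        data = rng.normal(size=(18, 4))
        from scipy.spatial.distance import pdist, squareform

        dist = DistanceMatrix(sample_ids(18), squareform(pdist(data)))
        opts = EvalOptions(L=5, seed=7)
        a = select_k_connectivity(dist, "kmeans", opts, features=data)
        b = select_k_connectivity(dist, "kmeans", opts, features=data)
        assert a.k == b.k and a.trace == b.trace
        assert np.array_equal(a.partition.labels, b.partition.labels)
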