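# pathdist — pathway-based distance score for expression heterogeneity

Unsupervised clustering of gene-expression profiles is a standard way to
look for disease subtypes ("endotypes"), but Euclidean distance over all
genes weights every gene equally, ignores the correlation of
functionally related genes, and drowns weak signals in transcriptome-wide
noise — a particular problem in chronic diseases, where expression
changes are far smaller than in cancer.  `pathdist` implements a
pathway-based distance score for this setting: samples are clustered once
per pre-defined pathway (e.g. the KEGG collections distributed as GMT
files) and the pairwise distance is the fraction of informative pathways
that disagree about a pair.

For expression matrix `G = (g_ij)_{M×N}` and pathways `P_1 … P_K`, each
pathway's member-gene submatrix is clustered with a multivariate Gaussian
mixture whose number of components `m_k` is selected by BIC (searching
spherical/diagonal/tied/full covariance families, k = 1…5).  The score
between samples `j1, j2` is

    d(j1, j2) = #{k : c_j1^k ≠ c_j2^k, m_k > 1} / #{k : m_k > 1},

where `c_j^k` is sample `j`'s cluster under pathway `k`; single-cluster
pathways do not vote.  The score matrix is then treated as a data matrix
(one column per subject) and re-embedded: the final distance is the
Euclidean distance between columns.  Samples are clustered on this
distance by K-means or average-linkage hierarchical clustering, with the
number of clusters chosen by the connectivity criterion (sum of `1/j`
penalties for j-th nearest neighbours falling outside a sample's
cluster).  Pathways larger than 10 matched genes can be handled by
downsampling: 100 random 10-gene subsets are clustered independently and
their votes combined.  A block-covariance simulator and a benchmark
harness reproduce the method's simulation study against plain Euclidean
distances, with no external data.

See `docs/methods.md` for the model, its assumptions, and every tunable.

## Worked example

Simulate a 120-sample cohort (three planted groups of 40) with 80
disjoint 10-gene pathways of which 25% carry the grouping (mean shift
δ = 1.5), score it, and evaluate against the planted truth:

```sh
pathdist simulate --n-pathways 80 --set-size 10 --delta 1.5 --p-w 0.25 \
    --m-total 3000 --seed 11 --out-dir sim
pathdist score --expr sim/expression.tsv --gmt sim/genesets.gmt \
    --seed 11 --out-dir scored
pathdist evaluate --dist scored/final_distance.tsv \
    --truth sim/truth_labels.tsv --seed 11 --out-dir eval
```

prints

```
wrote dataset (3000 genes x 120 samples) to sim
20 voting pathway(s); wrote score and final distance to scored
L: 10
linkage: average
purity_hierarchical: 1.0
purity_kmeans: 1.0
seed: 11
selected_k_hierarchical: 3
selected_k_kmeans: 3
```

All 20 of the perturbed pathways found more than one cluster and voted;
the connectivity criterion selects the true three groups under both
clustering methods, and purity 1.0 means every sample landed with its
planted group.  The per-k trace (`eval/criteria.tsv`) shows why:

```
method	k	connectivity	dunn
kmeans	2	0.0	0.7750632193866067
kmeans	3	0.0	4.351997747364258
kmeans	4	0.8	0.30220767655502445
kmeans	5	11.430555555555557	0.4062616689884986
```

connectivity is zero up to the true k (merging well-separated groups
puts no near neighbour across a cluster boundary) and rises as soon as a
tight group is split, so the selector takes the largest zero — k = 3 —
where the Dunn index also peaks.

`pathdist benchmark --config bench.yaml --out-dir out` runs a replicate
study over a (δ, ρ, B, p_G, p_W) grid comparing the pathway score against
Euclidean distances (see `docs/methods.md` for the config schema), and
`pathdist cluster` assigns labels from any distance matrix with `--k
auto` selection.

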