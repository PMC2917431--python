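# commscale

Multi-scale community structure and biological function in protein
interaction networks.

Protein–protein interaction (PPI) networks contain communities — groups of
proteins more densely wired to each other than to the rest of the network —
at many scales at once: protein complexes nest inside pathways, pathways
inside broader processes. `commscale` detects communities across a continuum
of scales, tests each one for *functional homogeneity* with a test that
controls for the confounding fact that interacting proteins are already more
functionally similar than random pairs, and asks which purely topological
properties of a community predict that it is functionally homogeneous.

## The model and the test

**Potts community detection.** A partition `s` of nodes into communities is
scored by the energy

    H(s; λ) = − Σ_{i≠j} ( B_ij − λ k_i k_j / (2W) ) δ(s_i, s_j)

where `B` is the adjacency matrix, `k_i` node degrees, `W` the edge count,
and the sum runs over ordered pairs of distinct nodes sharing a community.
The null term `k_i k_j / 2W` is the Newman–Girvan configuration model; at
`λ = 1`, minimizing `H` is ordinary modularity maximization.  The resolution
parameter `λ` is swept on a log₁₀ grid (default −1 to 3): small `λ` merges
everything into one community, large `λ` shatters the network into
singletons, and the interesting biology lives in between.  Minimization uses
a seeded Louvain-style greedy heuristic; community labels are matched across
adjacent resolutions by greedy best-Jaccard overlap so a community can be
followed as the scale changes.

**Functional homogeneity.** Each similarity measure `S` (shared-annotation
rarity `G` over an ontology DAG, the same statistic `M` over a flat
vocabulary, or knockout growth-profile correlation `C`) is z-scored over all
interacting pairs of the network:

    z_ij = (S_ij − μ) / σ

A community is called functionally homogeneous when the mean of `z_ij` over
its internal edges exceeds 0.3.  Because the mean (not the aggregate
`√n·mean`) is used, communities of different sizes — hence different scales —
are judged evenhandedly; 0.3 is anchored to the one-sided 5% normal critical
value for a community with 30 internal pairs (`z₀.₉₅/√30 ≈ 0.300`).

**Topology as a predictor.** Community-level metrics (mean clustering
coefficient, density, mean geodesic distance, …, 14 in all) are evaluated as
single-threshold classifiers of homogeneity via ROC curves; per-resolution
AUCs are averaged over `0 ≤ log λ ≤ 3`.

Everything runs on synthetic benchmarks with planted two-level community
structure and controlled annotation/growth signal, so every stage has ground
truth; readers for edge-list TSV, minimal OBO, annotation TSV and growth CSV
accept real exports of the same shape.

## Worked example

```python
from commscale import potts, homogeneity as hmg, topology, similarity
from commscale import classifier as clf
from commscale.synthetic_data import generate_mixed_benchmark

# network whose fine modules alternate dense+annotated / sparse+unannotated
net, structure, ann = generate_mixed_benchmark(seed=1)
sw = potts.sweep(net, 0.0, 3.0, 0.25, seed=1)
es = similarity.edge_similarity(net, "G", ann, all_pairs_sample=0, seed=1)
calls = hmg.call_communities(sw, {"G": hmg.zscore_edges(es)}, net)
table = topology.sweep_metrics(net, sw, ["mean_clustering", "mean_geodesic",
                                         "density", "mean_degree"])
print(clf.metric_ranking(clf.evaluate_metrics(table, calls, measure="G")))
```

prints

```
         metric measure  mean_auc  n_lambdas
    mean_degree       G  1.000000          4
mean_clustering       G  0.895833          4
        density       G  0.850694          4
  mean_geodesic       G  0.190972          4
```

Communities that are densely and locally wired (high mean degree, clustering,
density) are the functionally homogeneous ones (AUC well above the chance
level 0.5), while communities whose members are far apart (high mean geodesic
distance) are *anti*-predicted (AUC below 0.5 — predictive when below a
threshold, reported unflipped).

The same analysis is available from the shell; each subcommand is a thin
wrapper over one library stage:

```sh
commscale simulate --fidelity 1.0 --seed 5 --outdir data
commscale detect --edges data/edges.tsv --log-min -1 --log-max 3 --step 0.25 --seed 5 --out parts.csv
commscale homogeneity --sweep parts.csv --edges data/edges.tsv \
    --annotations data/annotations.tsv --ontology data/ontology.obo --measure G
commscale run-all --config config.yaml    # full pipeline from a YAML config
```

On a planted benchmark the sweep summary (written as `sweep_summary.csv`)
shows the characteristic profile: the few large communities at coarse
resolution are not homogeneous, and the count of proteins in homogeneous
communities peaks at the intermediate scale where the planted modules are
recovered, e.g.

```
 log10_lambda  n_communities  n_proteins  n_homog_G  n_proteins_homog_G
         -1.0              2          48          0                   0
         -0.5              2          48          0                   0
          0.0              4          48          4                  48
          0.5              8          44          8                  44
          1.0              0           0          0                   0
```

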