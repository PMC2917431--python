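# Methods

## Potts energy and its conventions

The quality function minimized is

    H(s; λ) = − Σ_{i≠j} J_ij(λ) δ(s_i, s_j),      J_ij(λ) = B_ij − λ R_ij,

with the Newman–Girvan null `R_ij = k_i k_j / (2W)`.  The pair sum runs over
*ordered pairs of distinct nodes*.  The literature is split on whether to sum
ordered or unordered pairs; the choice rescales `H` by a constant factor and
cannot move any optimum, so we fix ordered pairs and state it.  Under this
convention, a triangle collapsed into one community at `λ = 1` has
`H = −6·(1 − 4/6) = −2`, and `H = −2W·Q` with `Q` the Newman–Girvan
modularity.

Self-loops are retained in the `Network` container (they appear in real
interaction exports and in degree bookkeeping, where a self-loop contributes
2) but are excluded from community detection, connectivity and topology:
`δ(s_i, s_i) = 1` always, so a self-pair's energy term is identical in every
partition.

`λ = 0` is admitted for the limit check only; every connected network then
collapses into one community.  Once `λ > max_{edges} 2W/(k_i k_j)` every
`J_ij` on an edge is negative and the optimum is all singletons
(`singleton_lambda_bound` computes the bound).

## Optimizer

Minimization is NP-hard, so a two-phase greedy local search is used
(single-node moves to the neighboring community — or a fresh singleton — with
the largest energy decrease, then aggregation of communities into weighted
super-nodes, iterated to a local minimum).  Node visit order is shuffled by
the seed each pass; ties between equally improving moves break to the lowest
community label, which makes runs reproducible bit-for-bit.  Near-optimal
partitions of modular networks are massively degenerate, so tests compare
energies and recovered planted structure, never literal label sets, and the
optimizer is cross-checked in the test suite against (a) exhaustive
enumeration of all partitions on ≤ 8-node fixtures and (b) an independent
Louvain implementation at matched resolution.

**Sweep warm starts.** Optimizing the grid in increasing-λ order invites
reusing the previous partition as the starting point.  Pure warm starting
turned out to be subtly harmful: greedy single-node moves cannot split an
inherited community that is too coarse for the new resolution (every
single-node extraction crosses an energy barrier), which measurably degraded
planted-structure recovery.  The sweep therefore runs both a warm-started and
a cold (all-singletons) optimization per grid point and keeps the lower
energy; this dominates both pure modes at roughly twice the cold cost.
`warm_start=False` gives fully independent runs.

## Cross-resolution labels

To follow a community through the sweep, community labels are matched between
adjacent grid points by overlap: for fine-partition community `K_i` and
coarse-partition community `L_j`, `W_ij = |K_i ∩ L_j| / |K_i ∪ L_j|`
(Jaccard; a raw-intersection variant is provided and gives nearly identical
matchings).  Pairs are matched greedily in decreasing `W_ij`, each community
at most once — ties break to larger intersection, then lower label — and
unmatched fine communities receive fresh labels.  The coarsest partition
anchors the naming and matches propagate up the grid, so labels are globally
consistent; only names change, never co-membership.

## Similarity measures

**G (ontology).** Annotations are propagated to all DAG ancestors, excluding
the root; a protein annotated only with the root counts as unannotated.  For
a pair, `n_ij` counts proteins whose propagated set contains the pair's
shared set; `G_ij = 1 − n_ij/N`.  The empty shared set is vacuously contained
in every annotation set, so `n_ij = N` and `G_ij = 0`: missing annotation is
never penalized below the no-information level.  Any strictly decreasing
function of `n_ij/N` yields the same downstream calls up to re-normalization
of the z-scores; the form lives in one pluggable function
(`rarity_similarity`) so alternatives can be registered.

**M (flat vocabulary).** The same statistic over single-level terms, no
propagation — emulating top-level functional catalogues whose terms all sit
at one depth.

**C (growth profiles).** Pearson correlation of two knockout strains'
condition-response vectors, with elements `L_{i,t} =
log2(g_{i,t}/control_mean_i)` when raw rates are supplied.  Pearson r is
invariant to the log base, so only the ratio structure matters.
Zero-variance profiles yield an undefined correlation, reported as missing.
Pairs with a missing profile are dropped from the C edge set; pairs with an
unannotated member are *kept* (similarity 0) in G/M.

## Homogeneity test

Interacting pairs are more similar than random pairs, so a community — which
necessarily contains many interacting pairs — would look "enriched" under a
random-set null even if its wiring carried no functional information.  The
test therefore z-scores each interacting pair's similarity against the mean
and standard deviation of *all* interacting pairs (population convention,
divide by n: the pair set is the entire population, not a sample), and
scores a community by the mean z over its internal scored edges.

The call is `mean_z > 0.3`, strictly; the boundary case is configurable but
not homogeneous by default.  The threshold is anchored by the aggregate
z-score `√n·mean_z`: at `n = 30` internal pairs, the one-sided 5% critical
mean is `z₀.₉₅/√30 = 0.3003 ≈ 0.3`.  The aggregate statistic itself is
deliberately not used — it grows with community size, which would make
communities at different resolutions incomparable — so the call is not a
conventional significance test and no multiple-testing correction is applied.
The critical value is computed from the normal quantile function, never
hard-coded.

Communities with zero scored internal edges are excluded from calls rather
than counted as non-homogeneous: missing data is not negative evidence.
Reporting (summaries, ROC labels) is restricted to communities of size ≥ 4;
the filter is a reporting choice, not part of the test, and `min_size=1`
disables it (the per-protein trace uses unfiltered calls).

## Topology metrics

Fourteen community metrics are implemented: mean degree, degree
assortativity, mean clustering coefficient, mean geodesic betweenness, mean
closeness, mean eigenvector centrality (power iteration, tolerance 1e-8,
≤ 10⁴ iterations, non-convergence → missing), mean geodesic distance,
diameter, mean harmonic geodesic distance, efficiency, cyclomatic number
(E − V + components), density, fraction of articulation vertices, and largest
adjacency eigenvalue.  All are computed on the community's *induced
subgraph*: a topological proxy for functional homogeneity should reflect
intra-community wiring, not the embedding context.  A whole-network variant
of the node clustering coefficient is available behind a flag for sensitivity
checks.

Degenerate-input policy: node clustering is 0 for degree < 2 (keeping the
triangle/star examples well defined); geodesic means are over connected pairs
only; diameter is the maximum over components; efficiency is the mean inverse
geodesic over all ordered distinct pairs with disconnected pairs contributing
0, making it exactly the reciprocal of the harmonic-mean geodesic; metrics
undefined at a community's size (density or diameter of a singleton,
assortativity of a regular subgraph) are emitted as missing, and
missing-valued communities are dropped from that metric's ROC.

## ROC/AUC evaluation

Each metric is thresholded to predict homogeneity; sweeping the threshold
over observed values gives the ROC curve, and the trapezoidal AUC equals the
Mann–Whitney probability with ties credited 1/2 (the two routes are computed
independently and cross-checked in tests).  AUC < 0.5 is reported as-is — it
means the metric predicts homogeneity when *below* a threshold.  Per-λ AUCs
(undefined λs skipped and counted in a coverage report) are averaged
unweighted over `0 ≤ log λ ≤ 3`, excluding the coarse end where the handful
of communities makes single-class labels common.  Per the reporting filter,
only size ≥ 4 communities enter the ROC.

## Synthetic benchmarks

The generator plants a two-level hierarchy: `n_coarse` coarse modules, each
containing `fine_per_coarse` fine modules of `fine_size` nodes, with
independent edge probabilities `p_fine` (within fine), `p_coarse` (within
coarse, across fine) and `p_between` (elsewhere), requiring
`p_fine > p_coarse > p_between` (ties allowed only at exactly 0, which
switches a tier off).  Two levels suffice to exercise multi-resolution
recovery; deeper nesting would be a configuration extension.  The largest
connected component is returned, with ground-truth labels restricted to it.

Annotations use a three-level rooted tree (root → coarse-branch terms →
fine-module leaf-term sets, plus background terms under the root).  Each
protein receives its module's term set with probability *fidelity*, else a
single random background term — so infidelity produces sparse, uninformative
annotation rather than adversarial mislabeling, and unannotated-pair
semantics stay exercised.  Growth profiles are module-latent standard-normal
condition responses scaled by *effect_size* plus independent noise
(`noise_sd`), generated directly as log-ratios; a raw-rate writer
(`rates = control_mean · 2^L`) exercises the input transform.  A
`missing_fraction` of proteins carries no profile, mirroring the lethality
gap of real deletion screens; the default 418 conditions matches the size of
the published screen this emulates.  All randomness in a generator call flows
from one integer seed through a single `numpy.random.Generator`, so outputs
are byte-identical across reruns.

The mixed benchmark (`generate_mixed_benchmark`) alternates dense,
perfect-fidelity fine modules with sparse, zero-fidelity ones, coupling
wiring density to functional coherence; it is the testbed for the
metric-as-predictor question.

What the benchmarks do *not* emulate: the heavy-tailed degree sequence,
evidence-dependent edge noise, matrix/spoke expansion artifacts, annotation
depth heterogeneity, and the unknown true hierarchy depth of real interaction
data.  Passing tests demonstrate correctness and calibration of the machinery
under controlled signal, not performance claims about any particular real
network.

## Problem sizes and defaults

Analysis defaults: sweep grid −1 ≤ log₁₀ λ ≤ 3 (matching the 0.1–1000 range
where the method's behavior spans one-community to near-singleton
partitions), threshold 0.3, reporting size ≥ 4, evaluation window [0, 3].
Test and acceptance runs use grid step 0.25 and planted networks of 48–180
nodes — large enough that both planted scales are recovered with NMI ≥ 0.9
and small enough that the whole suite replays quickly; structure-recovery
checks use 4 × 3 × 15 nodes with p = 0.6/0.15/0.01, calibration and
concordance checks 3 × 2 × 10 with p = 0.8/0.15/0.01, annotation fidelity 1,
growth effect size 2 and noise 0.5 for the strong-signal condition.

## Known limitations

- The greedy optimizer is a local-minimum heuristic; on ambiguous instances
  different seeds give different near-optimal partitions (energies agree to
  within the degeneracy plateau).
- The shared-set similarity treats all terms equally; information-content
  weighting (Resnik/Lin) is out of scope.
- Identifier matching is exact-string; no alias resolution.
- Overlapping communities, weighted or directed edges, and
  simulated-annealing/spectral optimizers are out of scope.
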