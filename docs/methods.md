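# Methods

## Problem and model

Given an n × F numeric table, class labels known for a small fraction of
samples (the *labeled subset*, by default 10%), and no prior cluster count,
the package searches for (i) a binary feature mask, (ii) a set of K cluster
centers with 2 ≤ K ≤ Kmax, and (iii) the partition they induce.  The search
is a Pareto multiobjective optimisation: no scalar weighting of the
objectives is ever formed, and the optimiser returns an archive of mutually
non-dominated solutions from which one is selected using the labeled
subset.

### Point-symmetry distance

All distances are computed in the *active subspace* — the coordinates whose
mask bit is 1.  For a point x̄ and center c̄, the reflection of x̄ through c̄
is x̄* = 2c̄ − x̄; with d₁, …, d_knear the Euclidean distances from x̄* to
its knear nearest data points,

    d_sym(x̄, c̄) = (Σᵢ dᵢ) / knear,        d_ps(x̄, c̄) = d_sym · d_e(x̄, c̄),

with knear = 2 throughout.  "Nearest neighbours" are the knear nearest
points with pairwise distinct coordinates among all n points (the reflected
point is virtual and never indexed; x̄ itself may be a neighbour).
Neighbour queries go through an exact KD-tree; a dataset containing
coincident duplicate rows falls back to a deduplicated index so that
duplicates cannot inflate apparent symmetry.

Assignment: each point joins the cluster minimising d_ps provided the
corresponding d_sym is below θ, the maximum over all points of the
nearest-distinct-point distance; otherwise it joins the nearest Euclidean
center.  The gate exists because early in the search centers are poorly
placed and symmetry evidence is unreliable.  θ is recomputed per candidate
in its active subspace (all distances live there); computing it once over
the full feature space is available via `theta_scope="full"`.

### Objectives

* **Sym-index** (max): `Sym = D_K / (K · E_K)` with D_K the largest
  inter-center distance and E_K the summed point-symmetry distance of every
  point to its own cluster center, the reflected-point neighbours searched
  *within the cluster*.  The within-cluster search is deliberate: the index
  measures the symmetry of each cluster about its own center, whereas
  assignment-time d_ps asks whether *any* data support the reflection.
* **Xie–Beni index** (min): summed within-cluster squared Euclidean scatter
  over n times the squared minimum inter-center gap.
* **ARI** (max): Hubert–Arabie adjusted Rand index between the induced
  partition and the true classes, restricted to the labeled subset.  ARI is
  label-permutation invariant, so cluster ids never need to match class ids.
* **Feature count** (max): internal validity indices shrink with dimension
  (fewer active features ⇒ smaller distances), biasing wrapper selection
  toward tiny masks; maximising the active-feature count counteracts that
  bias.

A candidate is *degenerate* when its active-subspace centers coincide, a
cluster is empty, a cluster has fewer than knear coordinate-distinct
members, or E_K = 0.  Degenerate candidates are not discarded: they receive
the worst-case vector (Sym = 0, XB = 10¹², ARI = −1, features = 0) so the
annealer can pass through them.  The worst-case vector is dominated by
every valid solution and therefore never enters the archive.

### AMOSA

The annealer keeps an archive of mutually non-dominated solutions with a
soft limit SL and hard limit HL; when the archive outgrows SL it is
compressed to HL by single-linkage clustering of the (min-max normalised,
direction-aligned) objective vectors, keeping per cluster the member
nearest the cluster centroid.  The *amount of domination* between two
solutions is the product, over objectives where they differ, of the
range-normalised gaps, with ranges recomputed at each comparison from the
archive plus the two solutions (floored at 1e-12).  A dominated proposal is
accepted as the current point with probability p = 1/(1 + exp(Δdom_avg/T)),
averaging over the solutions that dominate it; incomparable proposals are
arbitrated against the archive; dominating proposals replace the current
point and update the archive, except that a proposal still dominated by an
archive member hands the chain to that member with probability ½ (the
member with the smallest amount of domination over the proposal).
Initialisation draws γ·SL random strings, hill-climbs each for `iter` steps
accepting only dominating mutants, and seeds the archive with the
non-dominated survivors.

We evaluated an alternative acceptance scale — the geometric mean of the
normalised gaps instead of their product, which cools the chain much more
sharply at a given temperature — and found it degraded archive quality on
the synthetic recovery task (the chain froze into local structure before
exploring the K/mask space), so the product form is kept.

### Mutation

Three moves, chosen uniformly: perturb every center coordinate with a
Laplace(μ = old value, scale δ = 1.0) draw; delete a uniformly chosen
center (K > 2 only); insert a uniformly chosen data point as a new center
(K < Kmax only).  Infeasible delete/insert degrade to perturb.  Every move
also flips each mask bit with probability 1/F (one expected flip per
mutation); an all-zero mask is redrawn uniformly.  Coordinates of inactive
features are carried and perturbed like any other so that a later mask flip
can reactivate a feature without losing center information.  The
no-feature-selection variant (`vamosa`) freezes the mask at all-ones.

Every fresh or mutated string is then refined by one K-means-style step
before it enters the search: points are assigned with the variant's
distance and each center is replaced by the mean of its cluster (empty
clusters keep their center; degenerate strings pass through unchanged).
This Lamarckian refinement, standard in the string-encoded clustering
family this method belongs to, is what makes short annealing schedules
converge: without it the archive accumulates members whose labeled-point
scores are perfect but whose centers are arbitrary, and the reported
partition — recomputed from those centers — degrades.  It can be disabled
(`center_update=False`) to study the raw operators.

### Selection of the reported solution

For each archive member the labeled points are assigned to the nearest
active-subspace Euclidean center and the Minkowski score against their true
classes is computed; the member with the smallest score wins.  With few
labeled points the score saturates at 0 for several members; exact ties are
broken by the largest Sym-index objective — archive order is search
history, not a meaningful preference, whereas the symmetry criterion is the
same one the unsupervised variants select by — and finally by lower index.
"Nearest center" at selection time is read as
plain Euclidean (not d_ps): selection is meant to be a cheap supervised
referee, and the Euclidean rule is the one the labeled points were scored
with in the baseline comparisons.  Unsupervised variants (`feaclus`,
`vamosa`) have no labeled referee and select the member with the largest
Sym-index, consistent with the method's symmetry emphasis; both rules are
overridable.  The reported partition is always recomputed from the selected
member's centers and mask, never cached mid-run.

## Parameters

| parameter | default | meaning |
|---|---|---|
| SL / HL | 100 / 50 | archive soft / hard limits (published setting) |
| iter | 50 | proposals per temperature, and hill-climb steps |
| Tmax / Tmin / α | 100 / 10⁻⁵ / 0.9 | geometric cooling schedule (153 levels) |
| γ | 2 | initial pool = γ·SL solutions |
| knear | 2 | reflected-point neighbours in d_sym |
| δ | 1.0 | Laplace scale of the center perturbation |
| flip prob | 1/F | per-bit mask flip probability |
| Kmax | round(√n) | soft upper bound on the cluster count |
| labeled fraction | 0.1 | share of samples with visible labels; count rounds half-even |

## Synthetic data

`generate_mixture` plants K clusters of unit within-cluster scale in
`relevant_d` dimensions: spherical Gaussians, axis-scaled ellipsoids
(axis σ pattern 1.0/0.3), or rings of radius 2 with 5% Gaussian radial
jitter — all point-symmetric about their centers, the geometry the distance
is designed for.  Cluster means sit on the coordinate axes (origin, s·e₀,
s·e₁, …, cycling axes with growing radius, s = `separation`): pairwise
center distances are ≥ s, and every relevant dimension separates some pair
of clusters, so no informative feature is redundant — dropping one merges
two clusters.  `noise_d` further columns are uniform over the relevant
data's bounding range, independent of the labels.  With separation 6 the
clusters are essentially non-overlapping, which is what the recovery tests
require; the generator does not emulate overlapping classes, correlated
noise features, heavy-tailed measurement error or missing values, so
passing recovery tests demonstrates correctness of the machinery, not
performance on messy real tables.

## Rank protocol

Scores (lower = better) from several algorithms on several datasets are
compared via *dense* within-row ranks (ties share the rank of their
distinct value), column-averaged.  The Friedman statistic is computed from
*mid-ranks* (average-style, tie-corrected), not dense ranks: dense ranks do
not sum to A(A+1)/2 per row, which the χ²_{A−1} reference distribution
assumes.  Both rank styles are exposed.  The package embeds the published
best-of-ten Minkowski scores of the six comparison algorithms on seven UCI
tables; on that table the printed per-row dense ranks and the first five
printed column averages (1, 2, 2, 3.28, 3.71) are reproduced exactly.  The
printed average of 6.2 for the K-means column is inconsistent with the
seven printed per-row ranks (which average 31/7 ≈ 4.43) and is treated as a
typo in the source table; the printed Friedman p of 0.0166 is likewise not
reproducible from those ranks under either tie convention, so neither is
asserted.  Nemenyi critical differences use tabulated q_α constants for
A = 2…10 at α ∈ {0.05, 0.10}.

## Numerical and scale choices

* Recovery experiments in the test-suite use n = 300, three spherical
  clusters, 2 informative + 3 noise features, separation 6, 10% labels, and
  a reduced schedule (SL = 40, HL = 20, iter = 20, Tmax = 10, Tmin = 0.01,
  α = 0.9; 66 temperature levels, ≈3·10³ objective evaluations per run) —
  the smallest configuration at which the search reliably explores the
  K/mask space.
* The stochastic-recovery check is a frequency statement (a majority of
  seeded runs recover K = 3, both informative features, ARI ≥ 0.8), not a
  per-run guarantee: a single annealing run at the reduced schedule fails
  with appreciable probability, which is also why results-style runs report
  the best of several restarts, mirroring the best-of-ten reporting of the
  benchmark scores.
* Oracle tests compare the KD-tree distance path against full pairwise
  scans at 1e-12, and ARI/Minkowski against explicit all-pairs enumeration.
* All ties (neighbour ranks, argmin over centers, selection) break toward
  the lower index; every source of randomness flows from one seeded
  generator, making whole runs bit-reproducible.

## Known limitations

* Runtime grows as O(n²K) per evaluation through the reflected-neighbour
  queries; tables beyond ~10⁴ samples need subsampling.
* The labeled Minkowski referee saturates: with few labeled points several
  archive members can score 0, and even with the Sym-index tie-break the
  selected member's unlabeled-data quality varies between seeds.
* θ per active subspace makes objective values of different masks live on
  different scales; the amount-of-domination normalisation absorbs most but
  not all of this.
* The Nemenyi constants table stops at 10 algorithms.
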