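# Methods

## The model

A fuzzy c-partition of N observations `x_1..x_N` in d dimensions is a
`k x N` matrix **U** with `u_ij ∈ [0,1]`, every column summing to 1 and
every row holding positive mass below N (no empty and no all-absorbing
cluster). The number of clusters k is unknown and is part of the search
space. Each candidate solution ("chromosome") is the pair `[U | g]` of the
membership matrix and a list of cluster tags; tags are renumbered 1..k after
every repair, and exist so that crossover can operate on whole clusters
rather than on scalar genes.

Cluster geometry is summarized per cluster by the fuzzified centroid
`μ_i = Σ_j u_ij^α x_j / Σ_j u_ij^α` and the fuzzy covariance
`Σ_i = Σ_j u_ij^α (x_j−μ_i)(x_j−μ_i)ᵀ / Σ_j u_ij^α`, with fuzzifier α > 1
(default 2). Four squared distances from a point to a cluster are supported,
all quadratic forms `(x−μ_i) M_i (x−μ_i)ᵀ`:

| metric       | M_i                      | geometry                              |
| ------------ | ------------------------ | ------------------------------------- |
| euclidean    | I                        | spherical clusters, equal volume      |
| mahalanobis  | Σ_i⁻¹                    | elliptical, scale-adaptive            |
| gk           | \|Σ_i\|^{1/d} Σ_i⁻¹      | elliptical, det-normalized (unit volume) |
| afc          | λ_i Σ_i⁻¹                | elliptical, volume term λ_i           |

λ_i defaults to the smallest eigenvalue of Σ_i (equivalently 1/largest
eigenvalue of Σ_i⁻¹); the reading of this adaptive term is genuinely open,
so it is pluggable (`DistanceSpec.afc_lambda`). Every Σ_i receives
`ε·trace(Σ_i)/d` on its diagonal before inversion (ε default 1e-8, or ε
itself for a zero-trace degenerate cluster), which keeps all metrics
positive definite for tiny or collinear clusters without affecting
well-conditioned ones.

## Objectives (all minimized)

- `fsse = Σ_i Σ_j u_ij^α d²(x_j, μ_i)` — compactness only.
- `xb = fsse / (N · min_{i≠j} sep(i,j))` — Xie-Beni; compactness over the
  worst centroid separation.
- `fs = fsse − Σ_i (Σ_j u_ij^α) d²(μ_i, μ*)` — Fukuyama-Sugeno, with μ*
  the unweighted mean of the k centroids; may be negative.
- `mdb = (1/k) Σ_i max_{j≠i} (S_i + S_j) / sep(i,j)` — a fuzzy
  Davies-Bouldin adaptation with **mass-normalized scatter**
  `S_i = Σ_t u_it^α d²(x_t,μ_i) / Σ_t u_it^α`.

Under the covariance-based metrics each cluster measures distances with its
own M_i, and the pairwise separation is
`sep(i,j) = min{ d²_i(μ_i,μ_j), d²_j(μ_i,μ_j) }`; under the Euclidean metric
it is simply `‖μ_i−μ_j‖²`. Coincident centroids (separation below 1e-12)
raise a degenerate-partition error from the public functions; inside the
evolutionary loop such individuals are scored +inf instead, so a transient
degenerate offspring never aborts a run.

Two deliberate choices here:

- **Normalized scatter in MDB.** The classical Davies-Bouldin index uses the
  *average* within-cluster dispersion. Using raw membership-weighted sums
  instead makes the index scale with cluster occupancy, which rewards
  splitting large clusters: on the unbalanced benchmark (scenario 2) the raw
  form decreases monotonically with k at fuzzy-C-means fixed points, so the
  true 3-cluster structure could never win. The mass-normalized form has its
  minimum at the generative k on scenarios 1 and 2, and reduces exactly to
  the classical index for crisp memberships (the crisp-limit equivalence is
  tested against an independent brute-force implementation).
- **Minimization throughout.** All four indices are quality measures for
  which smaller is better; rank fitness sorts ascending and "improvement"
  always means a lower index.

Rank-roulette selection assigns fitness `f_i = 2R_i/(ξ(ξ+1))` (best rank
R = ξ), a static probability vector summing to one; parents are drawn with
replacement from the cumulative intervals and redrawn until distinct. Ties
in objective value are broken by individual index so selection is
reproducible.

## The evolutionary loop

Per generation and per island (population ξ):

1. rank the population, build ξ offspring: with probability P_c(j) apply
   grouping crossover to a selected pair, otherwise copy the first parent;
2. apply split mutation then merge mutation, each with probability P_m(j)
   (cluster choice proportional to fuzzy row mass; split fraction
   ρ ~ U(0,1); both no-ops at the k bounds);
3. with probability P_b(j) run the local search (below);
4. elitism: the island's previous best replaces the worst offspring;
5. migration: with probability p_e per island, the island's best (chosen
   before any replacement this round) overwrites a random non-elite
   individual of a random other island.

P_c decays linearly from 0.8 to 0.6 over the TG generations, P_m grows from
0.05 to 0.1, and P_b decays from 0.1 to 0.05, so early generations explore
cluster structure while later ones exploit.

**Crossover repair.** After inheriting one parent's block verbatim and
scaling the other parent's block to each observation's remaining mass, the
offspring is repaired: clusters with near-zero mass (row sum < 1e-9) *and*
clusters to which no observation belongs maximally are removed, tags are
renumbered from 1, and columns are rescaled to unit sum (an observation
whose entire mass sat in removed clusters is assigned crisply to the
nearest surviving centroid under the active metric). The defuzzified
("argmax-support") emptiness test matters: a 1/k-averaged validity index
otherwise rewards carrying near-massless singleton clusters that are
invisible after defuzzification, and the cluster count ratchets to its upper
bound. If repair leaves fewer than 2 clusters or more than `k_max`, new
crossing points are drawn (at most 10 times) before falling back to a copy
of the first parent. The standalone `repair_chromosome` keeps the pure
mass-threshold rule by default; the argmax rule is opt-in.

**Local search.** Each trial proposes replacing all membership columns with
the columnwise-optimal assignment given the individual's *current* centroids
and metrics — `u_ij ∝ d_ij^{-2/(α-1)}`, the unique minimizer of the
compactness term per column — and keeps the proposal only if the active
objective strictly decreases, stopping at the first rejection or after
`local_search_trials` (default 20) accepted sweeps. The proposal is optimal
for compactness alone, so the acceptance gate is what keeps
separation-aware objectives honest. This design was chosen over random
column perturbations (flat-simplex redraws of single columns, blended
steps, and full random sweeps were all evaluated): random proposals have
vanishing acceptance probability near good solutions and stall the search
one to two orders of magnitude short of the index optima, which distorts
the inferred cluster count — a poorly-polished k=8 solution loses to a
poorly-polished k=12 one even when the index, evaluated at well-optimized
solutions, clearly prefers k=8.

**Randomness.** One master seed; island i draws from substream (seed, i) and
migration from substream (seed, S), so serial and parallel-island execution
would produce identical results, and every run is a pure function of
(dataset, config).

## Initialization and bounds

Each initial individual draws k uniformly from {k_min..k_init_max} (defaults
2..10) and every membership column from the flat Dirichlet; k may grow
through crossover up to k_max (default 15) and shrink to k_min (2). The
defaults ξ=20, S=4, TG=400 with the probability schedules above are the
reference configuration used by all benchmarks.

## Fuzzy C-means baseline and evaluation

The FCM baseline alternates the centroid and membership updates until the
largest membership change falls below 1e-6 or 300 sweeps, takes the best of
10 random starts by fuzzy SSE (centroids initialized at distinct random
observations), and handles a point coincident with centroids by splitting
its mass equally among them. Supervised evaluation always defuzzifies first
(maximal membership, ties to the lowest cluster index) and scores the crisp
labeling with the pair-counting Rand index `(TP+TN) / (N(N−1)/2)`, computed
exactly from the contingency table; it is checked against brute-force pair
enumeration and an independent library implementation in the tests.

## Synthetic benchmarks

Three two-dimensional Gaussian-mixture scenarios are built in, with class
labels retained for supervised scoring:

1. **Spherical** — 300 points, 8 equiprobable classes at means (−1,1),
   (2,−2), (1,0), (3,−1), (−1,−1), (−1,−3), (1,2), (3,1), all covariances
   0.35²·I.
2. **Unbalanced** — 400 points, class probabilities (0.5, 0.33, 0.17),
   means (0,2), (−1,−1), (2,−1), diagonal covariances diag(1², 0.8²),
   diag(0.6², 0.4²), diag(0.3², 0.5²).
3. **Heterogeneous** — 300 points, probabilities (0.1, 0.1, 0.1, 0.25,
   0.25, 0.2), means (−2,−2), (0,−2), (2,−2), (0,0.5), (−1.5,2), (2,2.5),
   covariances [[0.3,0.28],[0.28,0.3]], 0.02·I, [[0.3,−0.28],[−0.28,0.3]],
   0.46·I, 0.2·I, 0.5·I — correlated, anti-correlated, tiny and large
   clusters in one scene.

Class assignment is multinomial per observation (realized class sizes
fluctuate around their expectations), then coordinates are drawn from the
class Gaussian. A glyph generator (three jittered line-segment strokes
forming a capital "A"; 40 points per stroke, jitter 0.02) provides a small
stroke-segmentation fixture. All generators are pure functions of
(parameters, seed).

What these generators do *not* emulate: non-Gaussian shapes, outliers,
missing values, features on different scales, and dimensions beyond 2.
Passing benchmarks here shows the search and the indices recover planted
Gaussian structure; it does not certify behavior on messy real tables.

## Benchmark protocol

Reported quantities are medians of the Rand index and the modal final
cluster count over 5 replicates. One data set per study is generated from
the master seed and the algorithm is rerun on it with 5 derived run seeds:
the replicates average out run-to-run search variability, so the median
estimates the quantity a single run on one realization reports. (Replicating
the data as well was evaluated and rejected: cross-realization spread of the
medians — up to ±0.09 Rand on the heterogeneous scenario, where the index
optimum is bimodal in k across realizations — exceeds the ±0.03 band the
benchmark comparisons use, which would make the comparison test mostly a
test of which realizations were drawn.) Ties in the modal count resolve to
the smaller k. `scripts/acceptance.py` emits all
quantities as JSON; a full pass takes roughly 10 minutes on one CPU, with
single GGA runs (N=300-400, TG=400, S=4, ξ=20) taking 10-30 s depending on
the metric.

## Known limitations

- **Det-normalized metrics flatten the compactness-vs-k tradeoff.** Under
  the Gustafson-Kessel norm every cluster is unit-volume by construction, so
  merged super-clusters look almost as compact as their parts and the MDB
  optimum on heterogeneous data shifts toward few clusters (the AFC norm
  shares a milder form of the effect through its λ rescaling). On scenario 3
  the GK/AFC searches therefore settle at k=2-4 rather than the generative
  k=6, even though alternating optimization *at* k=6 under the GK metric
  recovers the planted structure almost perfectly. Selecting k with a
  det-normalized metric inside a Davies-Bouldin-style index is not a
  well-posed combination; prefer the Euclidean or Mahalanobis metric when
  the cluster count is itself in question.
- The Fukuyama-Sugeno index is supported but not exercised by the benchmark
  protocol beyond unit tests.
- Objective evaluation is O(k·N·d²) per individual and the loop is
  single-threaded; very large N calls for subsampling or a faster local
  search schedule.
- Memberships are dense; no sparse or out-of-core support.
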