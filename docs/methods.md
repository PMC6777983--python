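# Methods

This note records the models `tracenet` implements, the conventions and
numerical choices behind them, and what the synthetic data generator
does and does not emulate.

## Data model

A connectome is a directed weighted graph over `n` labeled regions.
Orientation is fixed package-wide: `A[i, j] = 1` means a projection from
source `i` to target `j`; every reader normalizes to this convention.
Self-loops are stripped on ingest with a warning. Weights must share
their support with the adjacency (`W > 0 ⇔ A = 1`).

Retrograde tracing probes *all* afferents of each injected region, so
only the injected-region subgraph is edge-complete and analyzable; the
in-degree of each injected region, however, can be counted over the full
source set. This **extended in-degree** `k_in_ext` (per construction at
least the within-subgraph in-degree, self-column excluded) is the
richness variable for the rich-club analysis.

Two weightings of labeled-neuron counts `p_ij` are supported:

- `w_ij = log(p_ij + 1)` — base 10 by default (counts are log-normal
  over ~5 decades; base-10 weights then read as "decades of neurons").
  The base is configurable because published analyses rarely state it.
- FLNe: `p_ij / N_ext(j)`, the fraction of labeled neurons extrinsic to
  injection `j`, which normalizes out tracer-uptake differences.
  An optional `flne_log` variant applies `log10(x + 1)` afterwards; this
  transform is the package's choice (it preserves support and
  monotonicity; no standard exists for log-scaled FLNe).

## Graph metrics

**Clustering.** Directed clustering follows Fagiolo's unified triangle
formulation. Per node, with `S = W^(1/3) + (W^(1/3))^T`:

    t_i = (S^3)_ii / 2
    C_i = t_i / [ d_i^tot (d_i^tot − 1) − 2 d_i^bidir ]

The default counts *all* directed triangle motifs ("total" variant);
binary clustering is the same formula on `A`. Weights enter raw — no
max-weight rescaling — so weighted clustering lives on the scale of the
weights (it equals the binary value when all weights are 1 and scales
linearly under uniform weight scaling). Nodes whose denominator is
non-positive (fewer than two distinct neighbors) score 0 and are
included in the network mean.

**Path lengths.** The binary characteristic path length is the mean
directed hop distance over ordered pairs. Weighted shortest paths
minimize summed inverse weights (`cost = 1/w`); `L^w` is the mean
minimal cost and `Lstep^w` the mean number of hops those cost-minimal
routes take. Ties between equal-cost routes are resolved toward fewer
hops, then lower node index, making `Lstep^w` deterministic. Unreachable
ordered pairs are excluded from the means and counted in a log message
(the intended use case, a ~66%-dense network, is strongly connected;
exclusion only matters for sparse synthetic edge cases).

## Null models and statistics

**Rewiring null.** Repeated double-edge swaps `(a→b, c→d) → (a→d, c→b)`,
rejecting self-loops and duplicate edges. Each weight stays attached to
its *target* slot (the weight that pointed into `b` still points into
`b`), so in-degree, out-degree and in-strength are conserved exactly on
every sample; out-strength is not (only in-strength is pinned by the
construction, matching how retrograde weights attach to the injected
region). Swap budget: 10 × edge count attempted swaps per sample
(configurable); the graph is returned unchanged, with a warning, when
complete. `k_in_ext` is inherited unchanged — it derives from sources
outside the subgraph, which rewiring does not touch — so rich-club
membership is identical across null samples and only internal wiring
varies.

**Weight-shuffle null.** The binary topology is fixed and the weight
multiset is permuted uniformly over the edges. Comparing a weighted
metric against this ensemble isolates the effect of *where* strengths
sit from the effect of the strength distribution itself.

**Normalization and p-values.** `X_norm = X / <X_null>`. Empirical p is
the plain proportion of null samples at least as extreme in the observed
direction (no +1 correction; a zero count is reported at the resolution
bound `1/n_samples`). Group comparisons use a two-sided permutation test
on the difference of means (random label reassignment). Multiple
comparisons are corrected by Benjamini–Hochberg FDR (statsmodels).
Ensemble sizes default to 10,000; routine runs and tests use 200–1,000
seeded samples.

## Modularity

Directed (weighted) modularity

    Q = (1/m) Σ_ij [ M_ij − k_i^out k_j^in / m ] δ(c_i, c_j)

with `M = A` or `W` and `m = Σ M`. Optimization is Leicht–Newman
spectral bisection on the symmetrized modularity matrix, refined by
Kernighan–Lin single-node moves, applied recursively with the standard
generalized-matrix correction until no split increases Q. The best of
`n_restarts` (default 100) randomized refinements is kept; exact ties
resolve to the lexicographically smallest canonical labeling, so results
are reproducible given a seed. Partition agreement uses the unadjusted
Rand index (pair-agreement fraction) with a permutation null (shuffling
one assignment over nodes) supplying chance calibration — an adjusted
index would double-count that correction.

## Rich club

    φ^b(k) = E_>k / (N_>k (N_>k − 1))
    φ^w(k) = W_>k / Σ_{r=1}^{E_>k} w_r^rank

where the club at threshold `k` is the set of nodes with `k_in_ext > k`,
`E_>k`/`W_>k` the count/total weight of connections inside it, and
`w^rank` the network's weights sorted descending (so `φ^w ≤ 1` always).
Clubs smaller than two nodes yield missing values, which propagate as
missing rather than zero. Both flavors are normalized against the
rewiring ensemble; per-threshold p-values (share of null samples with
`φ` at or above the observed) are FDR-corrected across the integer
threshold grid `min(k_in_ext) … max(k_in_ext)`. Hubs are the top
`ceil(0.20 n)` regions by `k_in_ext` (ties broken by label order,
logged); edges are classed rich (hub→hub), feeder (one hub endpoint) or
local, and mean-strength ratios between classes are permutation-tested
overall and within intra-/intermodular edges.

## Morphospace

A population (default 500; scaled runs use 30–50) of networks starts as
copies of the observed connectome. Each iteration: score every member on
normalized clustering and normalized path length, find the Pareto front
under the active objective pair (max C & min L for maximal small-world
organization, or the opposite), and replace each dominated member with a
mutated copy of a uniformly chosen front member. Front members persist
unmutated (elitism); because an all-identical population has no
dominated member at all, duplicate score points beyond their first
occurrence are also treated as replaceable — this is what sets the
exploration in motion and does not discard any distinct front point.
Mutations adjust four edges: two double-edge swaps under the regime's
conservation law (degree-preserving for the binary regime, additionally
in-strength-preserving for the weighted regime) or two weight-pair
exchanges on fixed topology (weight-only regime). The two objective
modes run as separate populations.

Normalization constants are computed once, from a null ensemble of the
*original* network, and reused for every candidate — per-candidate null
ensembles would multiply the cost by the ensemble size while only
rescaling the axes. Consequences: the observed network is a fixed,
bit-reproducible point in the space, and the dominated hypervolume
(measured against a fixed reference corner) is non-decreasing across
iterations, which the tests assert.

## Kuramoto dynamics

    dθ_i/dt = ω_i + λ Σ_j M_ji sin(θ_j − θ_i)

Incoming edges drive a region (`M_ji`: column `i` collects the afferents
of `i`, matching the source×target orientation). `ω_i ~ U[0, 1]` and
`θ_i(0) ~ U[−π, π]` are drawn fresh per realization. The weighted
coupling matrix is `W · ΣA/ΣW`, so total coupling matches the binary
matrix and the λ axis is comparable between modes; the weight-shuffled
mode draws a freshly shuffled network per realization.

Integration is fixed-step RK4 with `dt = 0.05`, horizon `T = 700`,
transient `τ = 300`, sampling every `0.5` time units (model units
throughout). The step was chosen so the convergence test (step-halving
on a 3-node cycle) confirms ≥ 3.8 observed order, and the λ = 0 case is
exact to 1e−10; absolute synchrony values at a given λ shift slightly
with `dt` and the `ω` scale, so cross-study comparisons should be made
on regime locations and ratio orderings, not raw values.

Summary statistics per λ: `r` (time-mean modulus of the mean phasor),
synchrony matrix `C_ij = |time-mean e^{i(θ_i−θ_j)}|` (discrete mean over
retained samples), `r_link` (off-diagonal mean of C), and the filter `F`
keeping the `round(N(N−1) r_link)` largest off-diagonal entries of C —
the *per-run* `r_link` sets the cutoff, ties at the cutoff break by
index order — averaged over runs as a synchronization probability.
Dynamical modularity is mean intra- over intermodular synchrony;
rich-club synchrony is mean hub–hub over all-other-pair synchrony, also
split by intra/intermodular pairs. Mode comparisons use the per-run
statistics in two-sided permutation tests with FDR across λ.

## Synthetic data generator

`SynthSpec` defaults encode the tract-tracing subgraph conditions:
29 regions, 66% directed density, raw counts log-normal(μ=3, σ=2)
floored to integers ≥ 1, two planted modules with a 2:1 intra/inter
edge-probability contrast (the strongest contrast feasible at this
density is ~3:1; 2:1 yields the weak modularity, Q ≈ 0.15, typical of
dense cortical graphs), a designated top-20% hub core whose internal
counts are doubled by default, and `k_in_ext = internal in-degree +
Binomial(62, density)` emulating afferents from 62 unobserved source
regions (hub regions draw their external afferents at a boosted rate so
the planted core tops the richness ranking). An optional exponential
distance rule multiplies counts by `exp(−d/λ_d)` for positions uniform
in the unit cube. Everything is driven by one seed; the same seed gives
a bit-identical network.

What it does *not* emulate: the real geometry and labels of cortical
areas, hemispheric structure, correlated weight placement within modules
(weights are independent of module membership except in the hub core),
or injection-specific tracer-uptake variability. Passing tests on
synthetic data therefore validate the *machinery* — conservation laws,
oracle agreement, planted-structure recovery, calibration on null
specs — not any empirical claim about real cortex; real-data values
attach to a user-supplied tracing matrix.

## Scaled-down problem sizes

Routine runs (tests, the acceptance script) use deliberately reduced
sizes, chosen as the package's own defaults for quick, reproducible
checks: null ensembles of 200–1,000 samples (10,000 remains the
production default), morphospace populations of 30–50 over 50–100
iterations (vs 500 × 1,000), and Kuramoto sweeps of ~5 couplings × 30–50
realizations (vs 21 × 1,000). The statistics these yield are coarser but
unbiased; every reported quantity is recomputed from scratch at run
time.

## Known limitations

- Modularity optimization is a heuristic; equal-Q partitions with
  different memberships exist, so comparisons should be made on Q values
  and module counts, not exact memberships.
- The swap-based null explores the degree-constrained graph space by a
  symmetric Markov chain; mixing is assumed adequate at 10× edge-count
  attempts but is not formally verified for every topology.
- Oscillators are identical and memoryless; no conduction delays, no
  regional heterogeneity, and the system ultimately approaches global
  synchrony for large λ.
- FLNe-weighted analyses share the pipeline but their log transform is a
  package convention (see above), so FLNe results should be read on that
  scale.
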