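# tracenet

Weighted and binary network analysis of directed tract-tracing
connectomes.

Retrograde tract-tracing datasets — most prominently the macaque
cortico-cortical matrix of Markov and colleagues (91 atlas regions, 29
injected regions, available from core-nets.org) — report not only which
inter-areal projections exist but how many labeled neurons each pathway
contains. `tracenet` is for researchers who want to ask what that
*connection strength* adds on top of the binary wiring diagram: does it
reinforce small-world, modular and rich-club organization, and does it
shape simulated functional synchrony?

## What it computes

Given a directed weighted connectome (rows = source region, columns =
target region, weights `w_ij = log10(p_ij + 1)` of labeled-neuron counts
`p_ij`, or FLNe fractions):

- **Graph metrics** — directed clustering `C^b`, `C^w` (Fagiolo "total"
  variant on raw weights), characteristic path lengths `L^b`, `L^w`
  (edge cost `1/w`) and the step length `Lstep^w` (hops taken by the
  cost-minimal routes).
- **Null models** — degree- and in-strength-preserving double-edge-swap
  randomization (weights stay attached to their target region, so
  in-strength is conserved exactly), weight-shuffled surrogates,
  normalized metrics `X_norm = X / <X_rand>`, empirical p-values,
  two-group permutation tests and Benjamini–Hochberg FDR.
- **Modularity** — directed (weighted) Leicht–Newman modularity
  `Q = (1/m) Σ_ij [M_ij − k_i^out k_j^in / m] δ(c_i, c_j)` optimized by
  spectral bisection with Kernighan–Lin refinement; Rand-index agreement
  between partitions with a permutation null; intra- vs intermodular
  strength contrasts.
- **Rich club** — binary `φ^b(k) = E_>k / (N_>k (N_>k − 1))` and weighted
  `φ^w(k) = W_>k / Σ_top-E w^rank` over the *extended* in-degree (afferents
  from the full source set), normalized against the rewiring null with FDR
  across thresholds; top-20% hub selection and rich/feeder/local strength
  contrasts.
- **Morphospace** — an evolutionary Pareto exploration of the
  (normalized clustering, normalized path length) plane under three
  mutation regimes (binary swaps, in-strength-preserving swaps,
  weight-only swaps), toward maximal or minimal small-world organization.
- **Kuramoto dynamics** — RK4 integration of
  `dθ_i/dt = ω_i + λ Σ_j M_ji sin(θ_j − θ_i)` over a coupling sweep, with
  order parameters `r` and `r_link`, pairwise synchrony matrix `C`,
  filtered synchrony probability `F`, dynamical modularity (intra/inter
  synchrony ratio) and rich-club synchrony ratios, compared across
  binary / weighted / weight-shuffled couplings.
- **Synthetic data** — a generator that emulates the tract-tracing
  statistics (29 regions, 66% density, log-normal counts, planted
  modules, a strong hub core, extended in-degree, optional exponential
  distance decay), so the whole pipeline is testable without downloads.

## Worked example

```python
import tracenet as tn

c = tn.generate(tn.SynthSpec(seed=1))           # 29 regions, ~66% density
print(tn.density(c))                            # 0.6711822660098522

cb = tn.clustering_binary(c)
lw, lstep = tn.path_length_weighted(c)
print(cb.network_value)                         # 0.68793810213325
print(lw.network_value, lstep.network_value)    # 0.7582251281225032 1.6379310344827587

part = tn.detect_modules(c, n_restarts=100, rng=0)
print(part.n_modules, round(part.Q, 3))         # 2 0.153

hubs = tn.select_hubs(c, fraction=0.2)
print(len(hubs.hubs))                           # 6
```

`density` is the fraction of the `n(n−1)` possible directed connections
present; `clustering_binary` the mean directed clustering; the weighted
path/step lengths the mean inverse-strength travel cost and the hops
those routes take; `Q` the directed modularity of the best partition
found; the hub set is the top 20% of regions by extended in-degree.

The same pipeline runs from the shell:

```sh
tracenet synth --seed 1 --out d
tracenet all --input d/net.csv --weighting none --fast --out results
```

For the real macaque matrix, pass the labeled-neuron count table
(sources × targets CSV from the public release) as `--input` with
`--weighting log_counts`.

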