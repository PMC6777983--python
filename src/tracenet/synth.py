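"""Synthetic connectomes with tract-tracing-like statistics, plus fixtures.

The generator emulates the statistical structure of a retrograde
tract-tracing subgraph: ~29 regions at ~66% directed density, raw
connection counts drawn log-normal (then log-transformed to weights),
planted modular structure, an optional strong hub core, an extended
in-degree vector mimicking afferents from unobserved atlas regions, and
an optional exponential decay of weight with distance (EDR).

``fixtures`` returns small hard-coded graphs (TOY4, TOY7, K4, RING5)
whose metrics the test-suite recomputes with brute-force oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Connectome, log_weight

__all__ = ["SynthSpec", "generate", "fixtures"]


@dataclass
class SynthSpec:
    """Parameters of the synthetic tract-tracing connectome.

    Defaults mirror the macaque edge-complete subgraph conditions:
    29 regions, 66% density, log-normal raw counts with log-mean 3 and
    log-sd 2, two planted modules with a 2:1 intra/inter edge-probability
    contrast (weak modularity, as in dense cortical graphs), a top-20% hub
    core whose internal counts are doubled, and 62 extra (unobserved)
    source regions feeding the extended in-degree.
    """

    n_nodes: int = 29
    density: float = 0.66
    weight_mu: float = 3.0
    weight_sigma: float = 2.0
    n_modules: int = 2
    module_contrast: float = 2.0  # p_intra / p_inter
    hub_fraction: float = 0.2
    hub_weight_mult: float = 2.0
    extra_sources: int = 62
    edr_lambda: float | None = None  # decay length in unit-cube distance
    log_base: float = 10.0
    seed: int | None = None

    def __post_init__(self):
        if not 0 < self.density <= 1:
            raise ValueError("density must lie in (0, 1]")
        if self.n_modules < 1 or self.module_contrast <= 0:
            raise ValueError("invalid module specification")
        if not 0 <= self.hub_fraction < 1:
            raise ValueError("hub_fraction must lie in [0, 1)")


def generate(spec: SynthSpec) -> Connectome:
    """Draw one synthetic connectome; fully determined by ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    labels = [f"R{i + 1:02d}" for i in range(n)]
    modules = np.arange(n) % spec.n_modules

    # solve intra/inter edge probabilities to hit the target density exactly
    same = (modules[:, None] == modules[None, :]) & ~np.eye(n, dtype=bool)
    diff = (modules[:, None] != modules[None, :])
    n_intra, n_inter = int(same.sum()), int(diff.sum())
    total = n * (n - 1)
    p_inter = spec.density * total / (n_inter + spec.module_contrast * n_intra)
    p_intra = spec.module_contrast * p_inter
    if p_intra > 1.0:
        raise ValueError("infeasible spec: required intra-module probability > 1")

    P = np.where(same, p_intra, np.where(diff, p_inter, 0.0))
    A = (rng.random((n, n)) < P).astype(np.int8)
    np.fill_diagonal(A, 0)

    counts = np.zeros((n, n))
    m = int(A.sum())
    raw = rng.lognormal(mean=spec.weight_mu, sigma=spec.weight_sigma, size=m)
    positions = rng.random((n, 3))  # drawn either way so seeds stay comparable
    if spec.edr_lambda is not None:
        dist = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=2)
        decay = np.exp(-dist / spec.edr_lambda)
        raw = raw * decay[A > 0]
    counts[A > 0] = np.maximum(1, np.floor(raw))

    if spec.hub_fraction > 0 and spec.hub_weight_mult != 1.0:
        n_hubs = int(np.ceil(spec.hub_fraction * n))
        hubs = np.arange(n_hubs)  # designated hub core: first nodes
        core = np.ix_(hubs, hubs)
        counts[core] = np.floor(counts[core] * spec.hub_weight_mult)

    W = log_weight(counts, base=spec.log_base)
    k_in_internal = A.sum(axis=0)
    k_in_ext = k_in_internal + rng.binomial(spec.extra_sources, spec.density, size=n)
    # give the designated hub core the largest external afferent counts too
    if spec.hub_fraction > 0 and spec.hub_weight_mult != 1.0:
        boost = rng.binomial(spec.extra_sources, min(1.0, spec.density * 1.4), size=n_hubs)
        k_in_ext[:n_hubs] = k_in_internal[:n_hubs] + np.maximum(
            boost, k_in_ext[:n_hubs] - k_in_internal[:n_hubs]
        )
    meta = {
        "generator": "synthetic_tracing",
        "spec": spec.__dict__.copy(),
        "positions": positions,
    }
    return Connectome(labels=labels, A=A, W=W, k_in_ext=k_in_ext, meta=meta)


def _toy(labels, edges, k_in_ext=None):
    n = len(labels)
    A = np.zeros((n, n), dtype=np.int8)
    W = np.zeros((n, n))
    for i, j, w in edges:
        A[i, j] = 1
        W[i, j] = w
    k_int = A.sum(axis=0)
    k = k_int if k_in_ext is None else np.asarray(k_in_ext)
    return Connectome(labels=list(labels), A=A, W=W, k_in_ext=k)


def fixtures() -> dict:
    """Hard-coded toy networks with oracle-checkable metrics.

    * TOY4 — 4 nodes, 7 weighted edges (integer "counts" stored in meta).
    * TOY7 — 7 nodes, 2 planted modules {0,1,2,3} and {4,5,6}, a 2-hub
      core (nodes 0, 1) with heavy mutual weights, and a fixed extended
      in-degree vector exceeding the internal in-degrees.
    * K4 — complete directed graph, unit weights.
    * RING5 — directed 5-cycle, unit weights.
    """
    toy4_counts = np.array(
        [
            [0, 9, 0, 3],
            [99, 0, 1, 0],
            [0, 9, 0, 0],
            [4, 0, 9, 0],
        ],
        dtype=float,
    )
    toy4 = Connectome(
        labels=["a", "b", "c", "d"],
        A=(toy4_counts > 0).astype(np.int8),
        W=log_weight(toy4_counts),
        k_in_ext=(toy4_counts > 0).sum(axis=0),
        meta={"counts": toy4_counts},
    )

    toy7_edges = [
        (0, 1, 5.0), (1, 0, 4.0),          # hub core, heavy
        (0, 2, 2.0), (2, 0, 1.0),
        (1, 3, 2.0), (3, 1, 1.5),
        (2, 3, 1.0), (3, 2, 0.5),
        (0, 3, 1.0),
        (4, 5, 1.0), (5, 6, 1.0), (6, 4, 1.0),  # second module ring
        (3, 4, 0.5), (6, 0, 0.5),               # intermodule bridges
    ]
    toy7 = _toy(
        "ABCDEFG",
        toy7_edges,
        k_in_ext=[6, 5, 3, 4, 2, 1, 1],
    )
    toy7.meta["planted_modules"] = [0, 0, 0, 0, 1, 1, 1]
    toy7.meta["planted_hubs"] = [0, 1]

    k4_edges = [(i, j, 1.0) for i in range(4) for j in range(4) if i != j]
    ring5_edges = [(i, (i + 1) % 5, 1.0) for i in range(5)]
    return {
        "TOY4": toy4,
        "TOY7": toy7,
        "K4": _toy("wxyz", k4_edges),
        "RING5": _toy("pqrst", ring5_edges),
    }
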