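"""Randomized reference networks and permutation statistics.

Two null families:

* ``rewire_preserving`` — repeated double-edge swaps that conserve every
  node's in-degree, out-degree and in-strength. A swap rewrites the edge
  pair (a->b, c->d) as (a->d, c->b); the weight that pointed *into* b
  stays on the new edge into b (and likewise for d), which is what makes
  in-strength conservation exact.
* ``shuffle_weights`` — the binary topology is held fixed and the multiset
  of weights is randomly permuted over the existing edges.

Plus the empirical normalization/p-value helper, a two-group permutation
test on mean difference, and Benjamini-Hochberg FDR (via statsmodels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .core import Connectome

logger = logging.getLogger("tracenet")

__all__ = [
    "NullEnsemble",
    "rewire_preserving",
    "shuffle_weights",
    "build_ensemble",
    "normalized_metric",
    "empirical_p",
    "permutation_test_groups",
    "fdr_bh",
]

DEFAULT_SWAP_MULTIPLIER = 10


@dataclass
class NullEnsemble:
    """Null-model metric distributions for one connectome.

    ``values`` maps metric name -> array of the metric evaluated on each
    of ``n_samples`` randomized networks.
    """

    kind: str  # "rewire_degree_instrength" | "weight_shuffle"
    n_samples: int
    seed: int | None
    values: dict = field(default_factory=dict)

    def mean(self, name: str) -> float:
        return float(np.nanmean(self.values[name]))

    def sd(self, name: str) -> float:
        return float(np.nanstd(self.values[name]))


def rewire_preserving(
    c: Connectome,
    n_swaps: int | None = None,
    rng: np.random.Generator | None = None,
) -> Connectome:
    """Degree- and in-strength-preserving randomization of a connectome.

    Attempts ``n_swaps`` double-edge swaps (default 10x the edge count),
    rejecting any swap that would create a self-loop or a duplicate edge.
    """
    rng = np.random.default_rng(rng)
    m = c.n_edges
    if m < 2:
        return c.copy()
    if m == c.n_nodes * (c.n_nodes - 1):
        logger.warning("graph is complete; no rewiring possible")
        return c.copy()
    if n_swaps is None:
        n_swaps = DEFAULT_SWAP_MULTIPLIER * m

    A = c.A.copy()
    W = c.W.copy()
    src, dst = np.nonzero(A)
    src, dst = src.tolist(), dst.tolist()
    picks = rng.integers(0, m, size=(n_swaps, 2))
    for e1, e2 in picks:
        if e1 == e2:
            continue
        a, b = src[e1], dst[e1]
        cc, d = src[e2], dst[e2]
        if a == d or cc == b or b == d:
            continue
        if A[a, d] or A[cc, b]:
            continue
        # weights follow their target endpoint: w(a->b) -> (c->b), w(c->d) -> (a->d)
        wb, wd = W[a, b], W[cc, d]
        A[a, b] = A[cc, d] = 0
        W[a, b] = W[cc, d] = 0.0
        A[a, d] = A[cc, b] = 1
        W[a, d] = wd
        W[cc, b] = wb
        dst[e1], dst[e2] = d, b
    out = c.copy()
    out.A, out.W = A, W
    out.meta["null"] = "rewire_degree_instrength"
    return out


def shuffle_weights(c: Connectome, rng: np.random.Generator | None = None) -> Connectome:
    """Random redistribution of the connection strengths over fixed topology."""
    rng = np.random.default_rng(rng)
    out = c.copy()
    idx = np.nonzero(c.A)
    w = c.W[idx]
    out.W[idx] = w[rng.permutation(len(w))]
    out.meta["null"] = "weight_shuffle"
    return out


def build_ensemble(
    c: Connectome,
    metrics: dict,
    kind: str = "rewire_degree_instrength",
    n_samples: int = 10_000,
    seed: int | None = None,
    n_swaps: int | None = None,
) -> NullEnsemble:
    """Evaluate named metric callables on ``n_samples`` null networks.

    ``metrics`` maps name -> callable(Connectome) -> scalar or array; array
    results are stacked along axis 0.
    """
    rng = np.random.default_rng(seed)
    values = {name: [] for name in metrics}
    for _ in range(n_samples):
        if kind == "rewire_degree_instrength":
            null = rewire_preserving(c, n_swaps=n_swaps, rng=rng)
        elif kind == "weight_shuffle":
            null = shuffle_weights(c, rng=rng)
        else:
            raise ValueError(f"unknown ensemble kind: {kind!r}")
        for name, fn in metrics.items():
            values[name].append(fn(null))
    return NullEnsemble(
        kind=kind,
        n_samples=n_samples,
        seed=seed,
        values={k: np.asarray(v, dtype=float) for k, v in values.items()},
    )


def empirical_p(observed: float, null_values: np.ndarray) -> float:
    """Proportion of null samples at least as extreme as the observation.

    The direction is taken from the observation itself: above the null mean
    counts samples >= observed, below counts samples <= observed. A zero
    proportion is reported as the resolution bound 1/n_samples.
    """
    null_values = np.asarray(null_values, dtype=float)
    null_values = null_values[np.isfinite(null_values)]
    if null_values.size == 0:
        return float("nan")
    if observed >= null_values.mean():
        p = np.mean(null_values >= observed)
    else:
        p = np.mean(null_values <= observed)
    return float(max(p, 1.0 / null_values.size)) if p == 0 else float(p)


def normalized_metric(
    c: Connectome,
    metric,
    ensemble: NullEnsemble,
    name: str | None = None,
) -> tuple[float, float]:
    """Observed/null-mean ratio and empirical p for one metric.

    ``metric`` is a callable(Connectome) -> scalar whose null distribution
    is stored in ``ensemble`` under ``name`` (default: the only key).
    """
    if name is None:
        if len(ensemble.values) != 1:
            raise ValueError("ensemble holds several metrics; pass name=")
        name = next(iter(ensemble.values))
    observed = float(metric(c))
    null = ensemble.values[name]
    mean_null = float(np.nanmean(null))
    if mean_null == 0:
        raise ZeroDivisionError("null mean is zero; ratio undefined")
    return observed / mean_null, empirical_p(observed, null)


def permutation_test_groups(
    values_a,
    values_b,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Two-sided permutation test on the difference of group means.

    Group labels are randomly reassigned ``n_perm`` times; p is the
    proportion of permutations whose absolute mean difference reaches the
    observed one.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    rng = np.random.default_rng(rng)
    observed = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    na = a.size
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        stat = abs(perm[:na].mean() - perm[na:].mean())
        if stat >= observed - 1e-12:
            count += 1
    return count / n_perm


def fdr_bh(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR: (adjusted p-values, rejection mask)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject
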