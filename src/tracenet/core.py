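"""Canonical data model for directed weighted connectomes.

Matrix orientation is fixed package-wide: rows are source regions, columns
are target regions, so ``A[i, j] == 1`` means a directed projection i -> j
(for retrograde tract tracing: neurons in source *i* labeled by an injection
in target *j*). All readers normalize to this orientation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("tracenet")

__all__ = [
    "Connectome",
    "RawTracing",
    "log_weight",
    "flne_weight",
    "edge_complete_subgraph",
    "density",
]


@dataclass
class Connectome:
    """A directed weighted brain network over ``n`` labeled regions.

    Attributes
    ----------
    labels : list of str
        Region identifiers, one per node.
    A : ndarray of shape (n, n)
        Binary adjacency, rows = source, columns = target, zero diagonal.
    W : ndarray of shape (n, n)
        Non-negative weights with the same support as ``A``.
    k_in_ext : ndarray of shape (n,)
        In-degree of each region counted over an *extended* source set
        (e.g. afferents from all 91 atlas regions onto the 29 injected
        ones), which dominates the within-subgraph in-degree.
    lobe : dict
        Optional region -> lobe tag map.
    meta : dict
        Free-form provenance.
    """

    labels: list
    A: np.ndarray
    W: np.ndarray
    k_in_ext: np.ndarray
    lobe: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.A = np.asarray(self.A)
        self.W = np.asarray(self.W, dtype=float)
        n = len(self.labels)
        if self.A.shape != (n, n) or self.W.shape != (n, n):
            raise ValueError("A and W must be n x n with n == len(labels)")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate region labels")
        self.A = (self.A != 0).astype(np.int8)
        if np.any(np.diag(self.A)) or np.any(np.diag(self.W)):
            raise ValueError("self-loops are not allowed (diag must be zero)")
        if np.any(self.W < 0):
            raise ValueError("weights must be non-negative")
        if not np.array_equal(self.W > 0, self.A > 0):
            raise ValueError("support(W) must equal support(A)")
        if self.k_in_ext is None:
            self.k_in_ext = self.in_degree.copy()
        self.k_in_ext = np.asarray(self.k_in_ext, dtype=int)
        if self.k_in_ext.shape != (n,):
            raise ValueError("k_in_ext must have one entry per node")
        if np.any(self.k_in_ext < self.in_degree):
            raise ValueError("k_in_ext must dominate the within-subgraph in-degree")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return int(self.A.sum())

    @property
    def in_degree(self) -> np.ndarray:
        return np.asarray(self.A.sum(axis=0)).astype(int)

    @property
    def out_degree(self) -> np.ndarray:
        return np.asarray(self.A.sum(axis=1)).astype(int)

    @property
    def in_strength(self) -> np.ndarray:
        return self.W.sum(axis=0)

    @property
    def out_strength(self) -> np.ndarray:
        return self.W.sum(axis=1)

    def copy(self) -> "Connectome":
        return Connectome(
            labels=list(self.labels),
            A=self.A.copy(),
            W=self.W.copy(),
            k_in_ext=self.k_in_ext.copy(),
            lobe=dict(self.lobe),
            meta=dict(self.meta),
        )


@dataclass
class RawTracing:
    """Labeled-neuron counts from retrograde tract-tracing experiments.

    ``counts[i, j]`` is the number of neurons in source region ``sources[i]``
    labeled by the injection in target region ``targets[j]``. The source set
    may exceed the injected set (91 atlas regions vs 29 injections).
    ``neurons_ext[j]`` is the total count of labeled neurons extrinsic to
    target j, the denominator of the FLNe weighting.
    """

    sources: list
    targets: list
    counts: np.ndarray
    neurons_ext: np.ndarray | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.sources), len(self.targets)):
            raise ValueError("counts must be len(sources) x len(targets)")
        if np.any(self.counts < 0):
            raise ValueError("labeled-neuron counts must be non-negative")
        if len(set(self.sources)) != len(self.sources):
            raise ValueError("duplicate source labels")
        if len(set(self.targets)) != len(self.targets):
            raise ValueError("duplicate target labels")
        if self.neurons_ext is None:
            # default denominator: total extrinsic label count per injection
            self.neurons_ext = self._extrinsic_sums()
        self.neurons_ext = np.asarray(self.neurons_ext, dtype=float)
        if np.any(self.neurons_ext + 1e-9 < self._extrinsic_sums()):
            raise ValueError("neurons_ext must be >= the extrinsic column sums")

    def _extrinsic_sums(self) -> np.ndarray:
        sums = self.counts.sum(axis=0).astype(float)
        for j, t in enumerate(self.targets):
            if t in self.sources:
                sums[j] -= self.counts[self.sources.index(t), j]
        return sums


def log_weight(counts: np.ndarray, base: float = 10.0) -> np.ndarray:
    """Log-transform labeled-neuron counts, ``w = log(p + 1)``.

    Tract-tracing counts span five orders of magnitude and are approximately
    log-normal, so the log of the count (plus one, keeping zeros at zero and
    preserving the support) is the standard connectivity weight. The base is
    configurable; base 10 is the package default.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    return np.log1p(counts) / math.log(base)


def flne_weight(raw: RawTracing) -> np.ndarray:
    """Fraction of labeled neurons extrinsic (FLNe).

    ``FLNe[i, j] = counts[i, j] / neurons_ext[j]`` — a target-wise
    normalization that compensates for variable tracer uptake across
    injections. Columns with no extrinsic label at all stay zero.
    """
    counts = raw.counts
    denom = np.asarray(raw.neurons_ext, dtype=float)
    bad = (denom <= 0) & (counts.sum(axis=0) > 0)
    if np.any(bad):
        raise ValueError("zero extrinsic-neuron denominator with nonzero counts")
    out = np.zeros_like(counts, dtype=float)
    pos = denom > 0
    out[:, pos] = counts[:, pos] / denom[pos]
    return out


def edge_complete_subgraph(
    raw: RawTracing,
    weighting: str = "log_counts",
    log_base: float = 10.0,
) -> Connectome:
    """Restrict the tracing matrix to the edge-complete injected subgraph.

    Only the injected (target) regions have been probed for *all* their
    afferents, so the targets x targets submatrix is the edge-complete graph
    the analysis runs on. The extended in-degree ``k_in_ext`` of each target
    keeps counting afferents from the full source set (self excluded),
    untouched by the restriction.

    Parameters
    ----------
    weighting : {"log_counts", "flne", "flne_log"}
        ``log_counts``: w = log(p+1); ``flne``: raw FLNe fractions;
        ``flne_log``: log(FLNe+1).
    """
    missing = [t for t in raw.targets if t not in raw.sources]
    if missing:
        raise ValueError(f"targets not present among sources: {missing}")
    if weighting == "log_counts":
        full_w = log_weight(raw.counts, base=log_base)
    elif weighting == "flne":
        full_w = flne_weight(raw)
    elif weighting == "flne_log":
        full_w = log_weight(flne_weight(raw), base=log_base)
    else:
        raise ValueError(f"unknown weighting: {weighting!r}")

    rows = [raw.sources.index(t) for t in raw.targets]
    W = full_w[rows, :].astype(float).copy()
    counts_sub = raw.counts[rows, :]
    if np.any(np.diag(counts_sub) > 0):
        logger.warning(
            "stripping %d self-loops from the tracing matrix",
            int((np.diag(counts_sub) > 0).sum()),
        )
    np.fill_diagonal(W, 0.0)
    A = (W > 0).astype(np.int8)

    # afferents from ALL sources, excluding the self-row
    nonzero = raw.counts > 0
    k_in_ext = nonzero.sum(axis=0).astype(int)
    for j, t in enumerate(raw.targets):
        i = raw.sources.index(t)
        if nonzero[i, j]:
            k_in_ext[j] -= 1

    return Connectome(
        labels=list(raw.targets),
        A=A,
        W=W,
        k_in_ext=k_in_ext,
        meta={"weighting": weighting, "n_sources": len(raw.sources)},
    )


def density(c: Connectome) -> float:
    """Directed connection density, edges / (n * (n - 1))."""
    n = c.n_nodes
    if n < 2:
        raise ValueError("density requires at least 2 nodes")
    return c.n_edges / (n * (n - 1))
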