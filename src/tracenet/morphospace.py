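"""Evolutionary Pareto morphospace in (normalized C, normalized L) space.

A population of networks, initialized as copies of the observed
connectome, is evolved toward one of two small-world trade-off corners:

* ``max_smallworld`` — maximize clustering, minimize path length;
* ``min_smallworld`` — the opposite corner.

Each iteration identifies the nondominated ("Pareto front") members,
replaces every dominated member with a mutated copy of a randomly chosen
front member (front members themselves persist unmutated), and repeats.
Mutations adjust four edges per replacement: two double-edge swaps under
the regime's conservation law, or — for the weight-only regime — two
exchanges of weight between edge pairs on the fixed topology.

Objectives are normalized once against reference constants (typically the
null-ensemble means of the original network), so the observed network is
a fixed point in the space and every sampled network is comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Connectome
from .metrics import clustering_binary, clustering_weighted, path_length_binary, path_length_weighted
from .nulls import rewire_preserving, shuffle_weights

__all__ = ["MorphospaceRun", "pareto_front", "mutate", "evolve", "hypervolume"]

REGIMES = ("binary_swap", "weighted_swap_instrength", "weight_only_swap")
MODES = ("max_smallworld", "min_smallworld")


@dataclass
class MorphospaceRun:
    regime: str
    mode: str
    c_ref: float
    l_ref: float
    seed: int | None
    population: list = field(default_factory=list)
    scores: np.ndarray | None = None  # (pop, 2): C_norm, L_norm
    trace: pd.DataFrame | None = None  # iteration, member, C_norm, L_norm, on_front
    hypervolumes: np.ndarray | None = None


def _orient(points: np.ndarray, mode: str) -> np.ndarray:
    """Map (C_norm, L_norm) so that larger is better on both axes."""
    pts = np.asarray(points, dtype=float).copy()
    if mode == "max_smallworld":  # want high C, low L
        pts[:, 1] = -pts[:, 1]
    elif mode == "min_smallworld":  # want low C, high L
        pts[:, 0] = -pts[:, 0]
    else:
        raise ValueError(f"unknown objective mode: {mode!r}")
    return pts


def pareto_front(points, mode: str = "max_smallworld") -> np.ndarray:
    """Boolean mask of nondominated points under the mode's orientation.

    A point is dominated when another is at least as good on both
    objectives and strictly better on one; exact duplicates do not
    dominate each other.
    """
    pts = _orient(np.atleast_2d(points), mode)
    n = len(pts)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        better_eq = (pts >= pts[i]).all(axis=1)
        strictly = (pts > pts[i]).any(axis=1)
        if np.any(better_eq & strictly):
            mask[i] = False
    return mask


def mutate(
    c: Connectome,
    regime: str,
    rng: np.random.Generator | None = None,
    n_pair_moves: int = 2,
) -> Connectome:
    """One mutation step: four edges adjusted under the regime's law.

    ``binary_swap`` and ``weighted_swap_instrength`` perform two successful
    double-edge swaps (degree-preserving; the weighted regime additionally
    conserves in-strength by keeping weights attached to their target
    slot). ``weight_only_swap`` exchanges the weights of two random edge
    pairs, leaving the topology untouched.
    """
    rng = np.random.default_rng(rng)
    if regime not in REGIMES:
        raise ValueError(f"unknown regime: {regime!r}")
    if regime == "weight_only_swap":
        out = c.copy()
        src, dst = np.nonzero(out.A)
        m = len(src)
        for _ in range(n_pair_moves):
            if m < 2:
                break
            e1, e2 = rng.choice(m, size=2, replace=False)
            i1, j1 = src[e1], dst[e1]
            i2, j2 = src[e2], dst[e2]
            out.W[i1, j1], out.W[i2, j2] = out.W[i2, j2], out.W[i1, j1]
        return out
    # topology regimes: two successful swaps, bounded attempts
    out = c.copy()
    done = 0
    for _ in range(100 * n_pair_moves):
        if done >= n_pair_moves:
            break
        trial = rewire_preserving(out, n_swaps=1, rng=rng)
        if not np.array_equal(trial.A, out.A):
            out = trial
            done += 1
    if regime == "binary_swap":
        # binary regime tracks topology only; weights stay uniform
        out.W = out.A.astype(float)
    return out


def hypervolume(points: np.ndarray, mode: str, ref: tuple[float, float]) -> float:
    """Area dominated by the nondominated subset, above a reference corner.

    ``ref`` is expressed in oriented coordinates (larger = better); points
    below the reference contribute nothing.
    """
    pts = _orient(np.atleast_2d(points), mode)
    pts = pts[pareto_front(points, mode)]
    pts = pts[(pts[:, 0] > ref[0]) & (pts[:, 1] > ref[1])]
    if len(pts) == 0:
        return 0.0
    order = np.argsort(-pts[:, 0])
    pts = pts[order]
    area, y_prev = 0.0, ref[1]
    for x, y in pts:
        if y > y_prev:
            area += (x - ref[0]) * (y - y_prev)
            y_prev = y
    return float(area)


def _objectives(c: Connectome, weighted: bool) -> tuple[float, float]:
    if weighted:
        cval = clustering_weighted(c).network_value
        lval = path_length_weighted(c)[0].network_value
    else:
        cval = clustering_binary(c).network_value
        lval = path_length_binary(c).network_value
    return cval, lval


def evolve(
    c: Connectome,
    regime: str,
    mode: str = "max_smallworld",
    pop: int = 500,
    iters: int = 1000,
    rng: np.random.Generator | int | None = None,
    c_ref: float | None = None,
    l_ref: float | None = None,
    n_ref_nulls: int = 200,
    trace_every: int = 1,
) -> MorphospaceRun:
    """Evolve a population toward (or away from) small-world organization.

    ``c_ref``/``l_ref`` are the normalization constants; when omitted they
    are estimated once as the mean clustering and path length of
    ``n_ref_nulls`` rewired versions of the original network.
    """
    rng = np.random.default_rng(rng)
    weighted = regime != "binary_swap"
    base = c.copy()
    if regime == "binary_swap":
        base.W = base.A.astype(float)

    if c_ref is None or l_ref is None:
        cs, ls = [], []
        for _ in range(n_ref_nulls):
            null = rewire_preserving(base, rng=rng)
            cv, lv = _objectives(null, weighted)
            cs.append(cv)
            ls.append(lv)
        c_ref = c_ref if c_ref is not None else float(np.mean(cs))
        l_ref = l_ref if l_ref is not None else float(np.mean(ls))

    population = [base.copy() for _ in range(pop)]
    raw = np.array([_objectives(base, weighted)] * pop)
    scores = raw / np.array([c_ref, l_ref])

    # fixed hypervolume reference: generously below/outside the start point
    start = _orient(scores[:1], mode)[0]
    hv_ref = (start[0] - 1.0, start[1] - 1.0)

    records = []
    hvs = []
    for it in range(iters + 1):
        on_front = pareto_front(scores, mode)
        hvs.append(hypervolume(scores, mode, hv_ref))
        if it % trace_every == 0 or it == iters:
            for member in range(pop):
                records.append((it, member, scores[member, 0], scores[member, 1], bool(on_front[member])))
        if it == iters:
            break
        # duplicates past the first occurrence are replaceable, otherwise an
        # identical initial population would never produce a dominated member
        seen: set = set()
        replace = ~on_front
        for member in range(pop):
            key = (scores[member, 0], scores[member, 1])
            if on_front[member]:
                if key in seen:
                    replace[member] = True
                seen.add(key)
        keep_idx = np.flatnonzero(on_front & ~replace)
        for member in np.flatnonzero(replace):
            parent = int(rng.choice(keep_idx))
            child = mutate(population[parent], regime, rng=rng)
            population[member] = child
            cv, lv = _objectives(child, weighted)
            scores[member] = (cv / c_ref, lv / l_ref)

    return MorphospaceRun(
        regime=regime,
        mode=mode,
        c_ref=c_ref,
        l_ref=l_ref,
        seed=None,
        population=population,
        scores=scores,
        trace=pd.DataFrame(records, columns=["iteration", "member", "C_norm", "L_norm", "on_front"]),
        hypervolumes=np.asarray(hvs),
    )
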