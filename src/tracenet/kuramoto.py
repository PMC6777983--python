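"""Kuramoto phase-oscillator dynamics on a connectome.

Each brain region i is a phase oscillator

    dtheta_i/dt = omega_i + lambda * sum_j M_ji sin(theta_j - theta_i)

driven by its *incoming* connections (M rows are sources, columns
targets, so column i of M collects the afferents of region i). Intrinsic
frequencies omega_i are uniform on [0, 1] and initial phases uniform on
[-pi, pi], drawn fresh for every realization. Integration is classic
fixed-step fourth-order Runge-Kutta; phases are sampled on the interval
[tau, T] after the transient.

Synchrony is summarized by the global order parameter r (time-averaged
modulus of the mean phasor), the pairwise synchrony matrix
C_ij = |time-mean of exp(i(theta_i - theta_j))|, its off-diagonal mean
r_link, and the filtered matrix F that keeps the N(N-1)*r_link largest
entries of C — averaged over realizations, F estimates the probability of
a region pair being synchronized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Connectome
from .modules import Partition
from .nulls import fdr_bh, permutation_test_groups, shuffle_weights
from .richclub import HubPartition

logger = logging.getLogger("tracenet")

__all__ = [
    "KuramotoConfig",
    "SyncResult",
    "simulate_run",
    "weighted_coupling",
    "order_parameters",
    "filtered_sync",
    "sweep",
    "compare_sweeps",
]


@dataclass
class KuramotoConfig:
    """Simulation settings: coupling grid, horizon, step and realizations."""

    lambda_grid: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.0, 0.1001, 0.005), 4)
    )
    T: float = 700.0
    tau: float = 300.0
    dt: float = 0.05
    sample_dt: float = 0.5
    n_runs: int = 1000
    seed: int | None = None

    def __post_init__(self):
        self.lambda_grid = np.asarray(self.lambda_grid, dtype=float)
        if not (0 < self.dt <= self.sample_dt):
            raise ValueError("need 0 < dt <= sample_dt")
        if not self.tau < self.T:
            raise ValueError("transient tau must precede the horizon T")


@dataclass
class SyncResult:
    """Per-coupling ensemble synchrony statistics for one network mode."""

    mode: str
    lambda_grid: np.ndarray
    r: np.ndarray
    r_link: np.ndarray
    C_mean: np.ndarray  # (n_lambda, N, N)
    F_mean: np.ndarray
    dyn_modularity: np.ndarray
    rc_ratio: np.ndarray
    rc_ratio_intra: np.ndarray
    rc_ratio_inter: np.ndarray
    per_run_r: np.ndarray  # (n_lambda, n_runs)
    per_run_dyn_mod: np.ndarray
    per_run_rc_ratio: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lambda": self.lambda_grid,
                "mode": self.mode,
                "r": self.r,
                "r_link": self.r_link,
                "dyn_modularity": self.dyn_modularity,
                "rc_ratio": self.rc_ratio,
                "rc_ratio_intra": self.rc_ratio_intra,
                "rc_ratio_inter": self.rc_ratio_inter,
            }
        )


def weighted_coupling(c: Connectome) -> np.ndarray:
    """Weights rescaled so total coupling equals that of the binary matrix.

    Keeping sum(M) == sum(A) makes the coupling-strength axis comparable
    between binary and weighted simulations.
    """
    total_w = c.W.sum()
    if total_w <= 0:
        raise ValueError("total weight is zero; cannot normalize coupling")
    return c.W * (c.A.sum() / total_w)


def simulate_run(
    coupling: np.ndarray,
    lam: float,
    config: KuramotoConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Integrate one realization; returns phases sampled on [tau, T].

    Output shape is (n_samples, N) with samples every ``config.sample_dt``.
    """
    M = np.asarray(coupling, dtype=float)
    if np.any(M < 0):
        raise ValueError("coupling matrix must be non-negative")
    n = len(M)
    Mt = M.T.copy()  # row i = afferents of node i
    omega = rng.uniform(0.0, 1.0, size=n)
    theta = rng.uniform(-np.pi, np.pi, size=n)

    def deriv(th):
        s, cth = np.sin(th), np.cos(th)
        return omega + lam * (cth * (Mt @ s) - s * (Mt @ cth))

    dt = config.dt
    n_steps = int(round(config.T / dt))
    stride = int(round(config.sample_dt / dt))
    first = int(round(config.tau / dt))
    samples = []
    for step in range(n_steps + 1):
        if step >= first and (step - first) % stride == 0:
            samples.append(theta.copy())
        if step == n_steps:
            break
        k1 = deriv(theta)
        k2 = deriv(theta + 0.5 * dt * k1)
        k3 = deriv(theta + 0.5 * dt * k2)
        k4 = deriv(theta + dt * k3)
        theta = theta + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(theta)):
            raise FloatingPointError(f"integration diverged at dt={dt}")
    return np.asarray(samples)


def order_parameters(phases: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Global order parameter r, link synchrony r_link, and matrix C."""
    phases = np.asarray(phases)
    if phases.ndim != 2 or phases.shape[0] < 2:
        raise ValueError("need >= 2 phase samples past the transient")
    E = np.exp(1j * phases)  # (t, n)
    r = float(np.mean(np.abs(E.mean(axis=1))))
    C = np.abs(E.T @ E.conj()) / phases.shape[0]
    np.fill_diagonal(C, 1.0)
    n = C.shape[0]
    off = ~np.eye(n, dtype=bool)
    r_link = float(C[off].mean())
    return r, r_link, C


def filtered_sync(C: np.ndarray, r_link: float) -> np.ndarray:
    """Binary filter keeping the round(N(N-1) * r_link) largest C entries.

    Ties at the cutoff resolved by flat index order (stable sort), so the
    filter is deterministic.
    """
    n = len(C)
    off = ~np.eye(n, dtype=bool)
    n_keep = int(round(n * (n - 1) * r_link))
    F = np.zeros_like(C)
    if n_keep <= 0:
        return F
    flat_idx = np.flatnonzero(off.ravel())
    vals = C.ravel()[flat_idx]
    order = np.argsort(-vals, kind="stable")
    keep = flat_idx[order[:n_keep]]
    F.ravel()[keep] = 1.0
    return F


def _pair_masks(n, partition: Partition | None, hubs: np.ndarray | None):
    off = ~np.eye(n, dtype=bool)
    intra = inter = hubpair = None
    if partition is not None:
        same = partition.assignment[:, None] == partition.assignment[None, :]
        intra = same & off
        inter = ~same & off
    if hubs is not None:
        is_hub = np.zeros(n, dtype=bool)
        is_hub[hubs] = True
        hubpair = is_hub[:, None] & is_hub[None, :] & off
    return off, intra, inter, hubpair


def _ratio(C, num_mask, den_mask) -> float:
    if num_mask is None or not num_mask.any() or not den_mask.any():
        return float("nan")
    return float(C[num_mask].mean() / C[den_mask].mean())


def sweep(
    c: Connectome,
    mode: str,
    config: KuramotoConfig,
    partition: Partition | None = None,
    hubs: HubPartition | None = None,
    rng: np.random.Generator | int | None = None,
) -> SyncResult:
    """Ensemble Kuramoto sweep over the coupling grid for one network mode.

    ``mode`` selects the coupling matrix: ``binary`` uses A, ``weighted``
    the strength-normalized W, and ``weight_shuffled`` draws a freshly
    weight-shuffled network for every realization. Module and rich-club
    synchrony ratios are evaluated on each run's C matrix and averaged.
    """
    rng = np.random.default_rng(rng if rng is not None else config.seed)
    if mode not in ("binary", "weighted", "weight_shuffled"):
        raise ValueError(f"unknown mode: {mode!r}")
    n = c.n_nodes
    hub_idx = hubs.hubs if hubs is not None else None
    if hubs is not None and len(hubs.hubs) == 0:
        raise ValueError("hub set is empty")
    off, intra, inter, hubpair = _pair_masks(n, partition, hub_idx)
    nonhub = off & ~hubpair if hubpair is not None else None

    n_lam = len(config.lambda_grid)
    shape_runs = (n_lam, config.n_runs)
    per_run_r = np.zeros(shape_runs)
    per_run_rlink = np.zeros(shape_runs)
    per_run_dm = np.full(shape_runs, np.nan)
    per_run_rc = np.full(shape_runs, np.nan)
    C_mean = np.zeros((n_lam, n, n))
    F_mean = np.zeros((n_lam, n, n))
    rc_intra = np.full(n_lam, np.nan)
    rc_inter = np.full(n_lam, np.nan)

    if mode == "binary":
        base_coupling = c.A.astype(float)
    else:
        base_coupling = weighted_coupling(c)

    for li, lam in enumerate(config.lambda_grid):
        rc_i_acc, rc_e_acc = [], []
        for run in range(config.n_runs):
            if mode == "weight_shuffled":
                coupling = weighted_coupling(shuffle_weights(c, rng=rng))
            else:
                coupling = base_coupling
            phases = simulate_run(coupling, lam, config, rng)
            r, r_link, C = order_parameters(phases)
            per_run_r[li, run] = r
            per_run_rlink[li, run] = r_link
            C_mean[li] += C
            F_mean[li] += filtered_sync(C, r_link)
            per_run_dm[li, run] = _ratio(C, intra, inter)
            if hubpair is not None:
                per_run_rc[li, run] = _ratio(C, hubpair, nonhub)
                if intra is not None:
                    rc_i_acc.append(_ratio(C, hubpair & intra, nonhub & intra))
                    rc_e_acc.append(_ratio(C, hubpair & inter, nonhub & inter))
        C_mean[li] /= config.n_runs
        F_mean[li] /= config.n_runs
        if rc_i_acc:
            rc_intra[li] = np.nanmean(rc_i_acc)
            rc_inter[li] = np.nanmean(rc_e_acc)

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN stats
        dyn_mod = np.nanmean(per_run_dm, axis=1)
        rc = np.nanmean(per_run_rc, axis=1)
    return SyncResult(
        mode=mode,
        lambda_grid=config.lambda_grid.copy(),
        r=per_run_r.mean(axis=1),
        r_link=per_run_rlink.mean(axis=1),
        C_mean=C_mean,
        F_mean=F_mean,
        dyn_modularity=dyn_mod,
        rc_ratio=rc,
        rc_ratio_intra=rc_intra,
        rc_ratio_inter=rc_inter,
        per_run_r=per_run_r,
        per_run_dyn_mod=per_run_dm,
        per_run_rc_ratio=per_run_rc,
    )


def compare_sweeps(
    a: SyncResult,
    b: SyncResult,
    stat: str = "per_run_r",
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    q: float = 0.05,
) -> pd.DataFrame:
    """Per-coupling permutation comparison of two sweeps, FDR across lambda."""
    rng = np.random.default_rng(rng)
    if not np.allclose(a.lambda_grid, b.lambda_grid):
        raise ValueError("sweeps use different coupling grids")
    pvals = []
    for li in range(len(a.lambda_grid)):
        va = getattr(a, stat)[li]
        vb = getattr(b, stat)[li]
        va, vb = va[np.isfinite(va)], vb[np.isfinite(vb)]
        pvals.append(
            permutation_test_groups(va, vb, n_perm=n_perm, rng=rng)
            if va.size and vb.size
            else np.nan
        )
    pvals = np.asarray(pvals)
    p_fdr = np.full_like(pvals, np.nan)
    ok = np.isfinite(pvals)
    if ok.any():
        p_fdr[ok] = fdr_bh(pvals[ok], q=q)[0]
    return pd.DataFrame(
        {"lambda": a.lambda_grid, "p_raw": pvals, "p_fdr": p_fdr, "stat": stat}
    )
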