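"""End-to-end analysis pipeline: metrics -> nulls -> modularity -> rich club
-> (optional) morphospace -> (optional) Kuramoto sweep.

One call, one :class:`~tracenet.io.ResultBundle`. Every stage logs one
line with its seed and problem size; any stage failure aborts with a
stage-named error after flushing the partial bundle.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, kuramoto, metrics, modules, morphospace, nulls, richclub
from .core import Connectome, edge_complete_subgraph
from .synth import SynthSpec, generate

logger = logging.getLogger("tracenet")

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    """Settings for one full analysis run."""

    input_path: str | None = None
    synth_spec: SynthSpec | None = None
    weighting: str = "log_counts"  # log_counts | flne | flne_log
    n_null: int = 10_000
    n_perm: int = 10_000
    n_restarts: int = 100
    hub_fraction: float = 0.20
    seed: int = 0
    run_morphospace: bool = False
    run_kuramoto: bool = False
    morphospace_pop: int = 500
    morphospace_iters: int = 1000
    kuramoto: kuramoto.KuramotoConfig = field(default_factory=kuramoto.KuramotoConfig)
    out_dir: str | None = None

    def scaled_down(self) -> "PipelineConfig":
        """A fast variant for smoke tests: small ensembles, short sweeps."""
        cfg = PipelineConfig(**{**self.__dict__})
        cfg.n_null, cfg.n_perm, cfg.n_restarts = 200, 200, 20
        cfg.morphospace_pop, cfg.morphospace_iters = 20, 20
        cfg.kuramoto = kuramoto.KuramotoConfig(
            lambda_grid=[0.0, 0.025, 0.05, 0.075, 0.1],
            T=200.0, tau=100.0, n_runs=10, seed=self.seed,
        )
        return cfg


def _load(config: PipelineConfig) -> Connectome:
    if config.input_path is not None:
        if config.weighting == "none":
            return io.read_connectome_csv(config.input_path)
        raw = io.read_tracing_csv(config.input_path)
        return edge_complete_subgraph(raw, weighting=config.weighting)
    if config.synth_spec is not None:
        return generate(config.synth_spec)
    raise ValueError("config needs either input_path or synth_spec")


def _stage(bundle, name):
    logger.info("stage %s starting", name)
    return time.time()


def run_all(config: PipelineConfig) -> io.ResultBundle:
    """Run the full weighted-vs-binary connectome analysis."""
    rng = np.random.default_rng(config.seed)
    bundle = io.ResultBundle(
        config={k: v for k, v in config.__dict__.items() if not hasattr(v, "__dict__")},
        seeds={"master": config.seed},
    )
    stage = "load"
    try:
        c = _load(config)
        bundle.metrics["n_nodes"] = c.n_nodes
        bundle.metrics["n_edges"] = c.n_edges
        bundle.metrics["density"] = c.n_edges / (c.n_nodes * (c.n_nodes - 1))

        stage = "metrics"
        t0 = _stage(bundle, stage)
        cb = metrics.clustering_binary(c)
        cw = metrics.clustering_weighted(c)
        lb = metrics.path_length_binary(c)
        lw, lstep = metrics.path_length_weighted(c)
        bundle.metrics.update(
            clustering_binary=cb.network_value,
            clustering_weighted=cw.network_value,
            path_length_binary=lb.network_value,
            path_length_weighted=lw.network_value,
            step_length_weighted=lstep.network_value,
        )
        logger.info("stage metrics done in %.1fs", time.time() - t0)

        stage = "null_normalization"
        t0 = _stage(bundle, stage)
        metric_fns = {
            "clustering_binary": lambda g: metrics.clustering_binary(g).network_value,
            "clustering_weighted": lambda g: metrics.clustering_weighted(g).network_value,
            "path_length_binary": lambda g: metrics.path_length_binary(g).network_value,
            "path_length_weighted": lambda g: metrics.path_length_weighted(g)[0].network_value,
        }
        rewire_seed = int(rng.integers(2**31))
        ens = nulls.build_ensemble(
            c, metric_fns, kind="rewire_degree_instrength",
            n_samples=config.n_null, seed=rewire_seed,
        )
        bundle.seeds["rewire_ensemble"] = rewire_seed
        for name, fn in metric_fns.items():
            norm, p = nulls.normalized_metric(c, fn, ens, name=name)
            bundle.null_summaries[name] = (ens.mean(name), ens.sd(name), p)
            bundle.metrics[f"{name}_norm"] = norm
        shuffle_seed = int(rng.integers(2**31))
        shuffle_fns = {
            k: metric_fns[k] for k in ("clustering_weighted", "path_length_weighted")
        }
        ens_sh = nulls.build_ensemble(
            c, shuffle_fns, kind="weight_shuffle",
            n_samples=config.n_null, seed=shuffle_seed,
        )
        bundle.seeds["shuffle_ensemble"] = shuffle_seed
        for name in shuffle_fns:
            norm, p = nulls.normalized_metric(c, metric_fns[name], ens_sh, name=name)
            bundle.null_summaries[f"{name}_vs_shuffled"] = (
                ens_sh.mean(name), ens_sh.sd(name), p,
            )
            bundle.metrics[f"{name}_vs_shuffled"] = norm
        logger.info("stage nulls done in %.1fs (n=%d)", time.time() - t0, config.n_null)

        stage = "modularity"
        t0 = _stage(bundle, stage)
        part_b = modules.detect_modules(
            c, weighted=False, n_restarts=config.n_restarts,
            rng=int(rng.integers(2**31)),
        )
        part_w = modules.detect_modules(
            c, weighted=True, n_restarts=config.n_restarts,
            rng=int(rng.integers(2**31)),
        )
        rand, rand_p = modules.rand_index(
            part_b.assignment, part_w.assignment, n_perm=config.n_perm, rng=rng
        )
        classes = modules.classify_edges_by_module(c, part_b)
        intra_w, inter_w = classes["intra_weights"], classes["inter_weights"]
        strength_ratio = float(np.mean(intra_w) / np.mean(inter_w)) if len(inter_w) else np.nan
        strength_p = (
            nulls.permutation_test_groups(intra_w, inter_w, n_perm=config.n_perm, rng=rng)
            if len(intra_w) and len(inter_w)
            else np.nan
        )
        bundle.metrics.update(
            modularity_binary_q=part_b.Q,
            modularity_binary_n_modules=part_b.n_modules,
            modularity_weighted_q=part_w.Q,
            modularity_weighted_n_modules=part_w.n_modules,
            rand_index=rand,
            rand_index_p=rand_p,
            intra_inter_strength_ratio=strength_ratio,
            intra_inter_strength_p=strength_p,
        )
        bundle.tables["partitions"] = pd.DataFrame(
            {
                "node": c.labels,
                "module_binary": part_b.assignment,
                "module_weighted": part_w.assignment,
            }
        )
        logger.info("stage modularity done in %.1fs", time.time() - t0)

        stage = "rich_club"
        t0 = _stage(bundle, stage)
        rc_seed = int(rng.integers(2**31))
        curve_b = richclub.rich_club_curves(
            c, flavor="binary", n_null=config.n_null, seed=rc_seed
        )
        curve_w = richclub.rich_club_curves(
            c, flavor="weighted", n_null=config.n_null, seed=rc_seed + 1
        )
        bundle.seeds["rich_club"] = rc_seed
        bundle.tables["rich_club_binary"] = curve_b.to_frame()
        bundle.tables["rich_club_weighted"] = curve_w.to_frame()
        hubs = richclub.select_hubs(c, fraction=config.hub_fraction)
        contrasts = richclub.class_strength_contrasts(
            c, hubs, partition=part_b, n_perm=config.n_perm, rng=rng
        )
        bundle.tables["class_strength_contrasts"] = contrasts
        bundle.metrics["n_hubs"] = len(hubs.hubs)
        sig_b = curve_b.k_grid[(curve_b.p_fdr < 0.05) & (curve_b.phi_norm > 1)]
        bundle.metrics["rich_club_sig_k_min"] = float(sig_b.min()) if sig_b.size else np.nan
        bundle.metrics["rich_club_sig_k_max"] = float(sig_b.max()) if sig_b.size else np.nan
        logger.info("stage rich_club done in %.1fs", time.time() - t0)

        if config.run_morphospace:
            stage = "morphospace"
            t0 = _stage(bundle, stage)
            frames = []
            for regime in morphospace.REGIMES:
                for mode in morphospace.MODES:
                    run = morphospace.evolve(
                        c, regime, mode=mode,
                        pop=config.morphospace_pop, iters=config.morphospace_iters,
                        rng=int(rng.integers(2**31)),
                    )
                    tr = run.trace.copy()
                    tr["regime"], tr["mode"] = regime, mode
                    frames.append(tr)
            bundle.tables["morphospace"] = pd.concat(frames, ignore_index=True)
            logger.info("stage morphospace done in %.1fs", time.time() - t0)

        if config.run_kuramoto:
            stage = "kuramoto"
            t0 = _stage(bundle, stage)
            sweeps = {}
            for mode in ("binary", "weighted", "weight_shuffled"):
                sweeps[mode] = kuramoto.sweep(
                    c, mode, config.kuramoto, partition=part_b, hubs=hubs,
                    rng=int(rng.integers(2**31)),
                )
            frames = [s.to_frame() for s in sweeps.values()]
            comp = kuramoto.compare_sweeps(
                sweeps["weighted"], sweeps["weight_shuffled"],
                n_perm=min(config.n_perm, 1000), rng=rng,
            )
            bundle.tables["kuramoto_sweep"] = pd.concat(frames, ignore_index=True)
            bundle.tables["kuramoto_weighted_vs_shuffled"] = comp
            logger.info("stage kuramoto done in %.1fs", time.time() - t0)

    except Exception as err:
        if config.out_dir:
            io.write_report(bundle, Path(config.out_dir))
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    if config.out_dir:
        io.write_report(bundle, Path(config.out_dir))
    return bundle
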