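import numpy as np
import pytest

import tracenet as tn
from tracenet.kuramoto import KuramotoConfig


def cfg(**kw):
    defaults = dict(lambda_grid=[0.0], T=50.0, tau=25.0, dt=0.05, sample_dt=0.5, n_runs=1)
    defaults.update(kw)
    return KuramotoConfig(**defaults)


class TestSimulateRun:
    def test_uncoupled_oscillators_advance_linearly(self):
        # lambda = 0: theta_i(t) = theta_i(0) + omega_i t, RK4 is exact
        config = cfg(T=20.0, tau=0.0)
        rng = np.random.default_rng(0)
        M = np.zeros((3, 3))
        # reproduce the generator's draws to know omega and theta0
        probe = np.random.default_rng(0)
        omega = probe.uniform(0, 1, 3)
        theta0 = probe.uniform(-np.pi, np.pi, 3)
        phases = tn.simulate_run(M, 0.0, config, rng)
        times = np.arange(0, 20.0 + 1e-9, 0.5)
        expected = theta0[None, :] + omega[None, :] * times[:, None]
        assert np.allclose(phases, expected, atol=1e-10)

    def test_two_oscillator_lock_threshold(self):
        # bidirectional pair: phase difference obeys d' = dw - 2 lam sin(d),
        # locking iff |dw| < 2 lam. Measure the drift of the difference just
        # above and below threshold and check the transition within 5%.
        M = np.array([[0.0, 1.0], [1.0, 0.0]])
        lam = 0.25
        threshold = 2 * lam

        def locked(dw):
            config = cfg(T=400.0, tau=300.0, dt=0.02)

            class FixedRng:
                def uniform(self, lo, hi, size):
                    if lo == 0.0:  # omega draw
                        return np.array([0.5 + dw / 2, 0.5 - dw / 2])
                    return np.array([0.0, 0.1])  # initial phases

            phases = tn.simulate_run(M, lam, config, FixedRng())
            d = phases[:, 0] - phases[:, 1]
            drift = abs(d[-1] - d[0]) / (phases.shape[0] * 0.5)
            return drift < 1e-3

        assert locked(threshold * 0.95)
        assert not locked(threshold * 1.05)

    def test_identical_frequencies_fully_synchronize(self):
        rng = np.random.default_rng(3)
        n = 5
        A = np.ones((n, n)) - np.eye(n)

        class SameOmega:
            def uniform(self, lo, hi, size):
                if lo == 0.0:
                    return np.full(n, 0.5)
                return np.linspace(-1, 1, n)

        phases = tn.simulate_run(A, 1.0, cfg(T=100.0, tau=80.0), SameOmega())
        r, r_link, C = tn.order_parameters(phases)
        assert r > 0.999
        assert np.all(C > 0.999)

    def test_rk4_convergence_order(self):
        # step-halving on a 3-node chain: error ratio ~ 2^4
        M = np.array([[0, 1.0, 0], [0, 0, 1.0], [1.0, 0, 0]])

        def final_theta(dt):
            class Fixed:
                def uniform(self, lo, hi, size):
                    if lo == 0.0:
                        return np.array([0.3, 0.6, 0.9])
                    return np.array([0.1, -0.5, 1.2])

            config = KuramotoConfig(lambda_grid=[0.0], T=10.0, tau=10.0 - dt,
                                    dt=dt, sample_dt=dt, n_runs=1)
            return tn.simulate_run(M, 0.8, config, Fixed())[-1]

        ref = final_theta(0.00125)
        e1 = np.linalg.norm(final_theta(0.02) - ref)
        e2 = np.linalg.norm(final_theta(0.01) - ref)
        order = np.log2(e1 / e2)
        assert order >= 3.8

    def test_divergence_raises_named_error(self):
        M = np.full((2, 2), 1e300)
        np.fill_diagonal(M, 0)
        with pytest.raises(FloatingPointError):
            tn.simulate_run(M, 1e300, cfg(T=1.0, tau=0.0), np.random.default_rng(0))


class TestWeightedCoupling:
    def test_uniform_weights_return_adjacency(self, toy7):
        c = toy7.copy()
        c.W = c.A * 3.0
        assert np.allclose(tn.weighted_coupling(c), c.A)

    def test_total_equals_edge_count(self, macaque_like):
        M = tn.weighted_coupling(macaque_like)
        assert M.sum() == pytest.approx(macaque_like.n_edges)

    def test_toy7_scalar_rescale_oracle(self, toy7):
        M = tn.weighted_coupling(toy7)
        scale = toy7.A.sum() / toy7.W.sum()
        for i in range(7):
            for j in range(7):
                assert M[i, j] == pytest.approx(toy7.W[i, j] * scale)


class TestOrderParameters:
    def test_identical_constant_phases(self):
        phases = np.full((10, 4), 1.3)
        r, r_link, C = tn.order_parameters(phases)
        assert r == pytest.approx(1.0)
        assert r_link == pytest.approx(1.0)
        assert np.allclose(C, 1.0)

    def test_four_static_phases_cancel(self):
        row = np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2])
        phases = np.tile(row, (8, 1))
        r, _, _ = tn.order_parameters(phases)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_drifting_pair_decorrelates(self):
        # relative phase sweeps uniformly over full cycles -> C_12 ~ 0
        t = np.arange(200)
        phases = np.stack([0.0 * t, 2 * np.pi * t / 100.0], axis=1)
        # discrete-sum oracle
        expected = abs(np.mean(np.exp(1j * (phases[:, 0] - phases[:, 1]))))
        _, _, C = tn.order_parameters(phases)
        assert C[0, 1] == pytest.approx(expected, abs=1e-12)
        assert C[0, 1] < 1e-10

    def test_global_phase_shift_invariance(self, rng):
        phases = rng.uniform(-np.pi, np.pi, size=(50, 6)) + np.cumsum(
            rng.random((50, 1)), axis=0
        )
        r1, rl1, C1 = tn.order_parameters(phases)
        r2, rl2, C2 = tn.order_parameters(phases + 1.234)
        assert r1 == pytest.approx(r2)
        assert rl1 == pytest.approx(rl2)
        assert np.allclose(C1, C2)


class TestFilteredSync:
    def test_rlink_one_keeps_all(self):
        C = np.random.default_rng(0).random((4, 4))
        np.fill_diagonal(C, 1)
        F = tn.filtered_sync(C, 1.0)
        off = ~np.eye(4, dtype=bool)
        assert F[off].sum() == 12

    def test_rlink_zero_keeps_none(self):
        C = np.eye(3)
        assert tn.filtered_sync(C, 0.0).sum() == 0

    def test_top_two_of_three_by_sort_oracle(self):
        C = np.array(
            [[1.0, 0.9, 0.2], [0.8, 1.0, 0.3], [0.4, 0.5, 1.0]]
        )
        F = tn.filtered_sync(C, 1 / 3)  # keep round(6/3)=2 largest
        assert F.sum() == 2
        assert F[0, 1] == 1 and F[1, 0] == 1  # 0.9 and 0.8 are largest


class TestSweep:
    def test_zero_coupling_ratios_near_one(self, macaque_like):
        part = tn.detect_modules(macaque_like, n_restarts=3, rng=0)
        hubs = tn.select_hubs(macaque_like)
        config = cfg(lambda_grid=[0.0], T=300.0, tau=100.0, n_runs=30)
        res = tn.sweep(macaque_like, "weighted", config, partition=part, hubs=hubs, rng=1)
        assert res.r_link[0] < 0.25
        assert res.dyn_modularity[0] == pytest.approx(1.0, abs=0.1)
        assert res.rc_ratio[0] == pytest.approx(1.0, abs=0.25)

    def test_synchrony_increases_with_coupling(self, macaque_like):
        config = cfg(lambda_grid=[0.0, 0.1], T=200.0, tau=100.0, n_runs=10)
        res = tn.sweep(macaque_like, "weighted", config, rng=2)
        assert res.r[1] > res.r[0] + 0.2

    def test_disconnected_modules_synchronize_internally(self):
        c = tn.generate(tn.SynthSpec(n_nodes=12, extra_sources=10, seed=8))
        # two disconnected 6-cliques
        A = np.zeros((12, 12))
        A[:6, :6] = 1
        A[6:, 6:] = 1
        np.fill_diagonal(A, 0)
        c = tn.Connectome([f"n{i}" for i in range(12)], A, A.astype(float), A.sum(axis=0))
        part = tn.Partition(np.array([0] * 6 + [1] * 6), 0.0)
        config = cfg(lambda_grid=[0.08], T=300.0, tau=200.0, n_runs=10)
        res = tn.sweep(c, "binary", config, partition=part, rng=3)
        assert res.dyn_modularity[0] > 1.5

    def test_shuffled_equals_weighted_for_uniform_weights(self, rng):
        c = tn.generate(tn.SynthSpec(n_nodes=10, extra_sources=10, seed=9))
        c.W = c.A.astype(float) * 2.0
        config = cfg(lambda_grid=[0.05], T=150.0, tau=75.0, n_runs=40)
        res_w = tn.sweep(c, "weighted", config, rng=4)
        res_s = tn.sweep(c, "weight_shuffled", config, rng=5)
        from scipy.stats import ks_2samp

        p = ks_2samp(res_w.per_run_r[0], res_s.per_run_r[0]).pvalue
        assert p > 0.01

    def test_empty_hub_set_errors(self, macaque_like):
        import dataclasses

        hubs = tn.select_hubs(macaque_like)
        empty = dataclasses.replace(hubs, hubs=np.array([], dtype=int))
        with pytest.raises(ValueError):
            tn.sweep(macaque_like, "binary", cfg(n_runs=1), hubs=empty, rng=0)
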