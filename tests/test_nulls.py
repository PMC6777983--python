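import numpy as np
import pytest

import tracenet as tn
from oracles import random_connectome


class TestRewirePreserving:
    def test_complete_graph_unchanged(self, k4):
        out = tn.rewire_preserving(k4, rng=np.random.default_rng(0))
        assert np.array_equal(out.A, k4.A)

    def test_two_edge_graph_swap_state(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[2, 3] = 1
        W = np.where(A > 0, [[0, 2.0, 0, 0], [0] * 4, [0, 0, 0, 5.0], [0] * 4], 0.0)
        c = tn.Connectome(list("abcd"), A, np.asarray(W), A.sum(axis=0))
        # only two reachable states: original or {0->3 (w 5), 2->1 (w 2)}
        seen = set()
        for seed in range(30):
            out = tn.rewire_preserving(c, n_swaps=1, rng=np.random.default_rng(seed))
            edges = tuple(sorted(zip(*np.nonzero(out.A))))
            seen.add(edges)
            assert np.allclose(out.in_strength, c.in_strength)
            assert np.array_equal(out.in_degree, c.in_degree)
            assert np.array_equal(out.out_degree, c.out_degree)
        assert ((0, 3), (2, 1)) in seen  # the swapped state is reachable

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation_on_toy7_samples(self, toy7, seed):
        out = tn.rewire_preserving(toy7, rng=np.random.default_rng(seed))
        assert np.array_equal(out.in_degree, toy7.in_degree)
        assert np.array_equal(out.out_degree, toy7.out_degree)
        assert np.allclose(out.in_strength, toy7.in_strength)
        assert np.all(np.diag(out.A) == 0)

    def test_topology_actually_changes(self, macaque_like):
        out = tn.rewire_preserving(macaque_like, rng=np.random.default_rng(1))
        assert np.any(out.A != macaque_like.A)


class TestShuffleWeights:
    def test_single_edge_identity(self):
        A = np.array([[0, 1], [0, 0]])
        c = tn.Connectome(["a", "b"], A, A * 3.0, A.sum(axis=0))
        out = tn.shuffle_weights(c, np.random.default_rng(0))
        assert np.array_equal(out.W, c.W)

    def test_multiset_and_topology_conserved(self, toy7, rng):
        out = tn.shuffle_weights(toy7, rng)
        assert np.array_equal(out.A, toy7.A)
        assert np.allclose(np.sort(out.W[out.A > 0]), np.sort(toy7.W[toy7.A > 0]))

    def test_three_edge_permutations_uniform(self):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 2] = A[2, 0] = 1
        W = np.zeros((3, 3))
        W[0, 1], W[1, 2], W[2, 0] = 1.0, 2.0, 3.0
        c = tn.Connectome(list("abc"), A, W, A.sum(axis=0))
        rng = np.random.default_rng(7)
        n = 10_000
        counts = {}
        for _ in range(n):
            out = tn.shuffle_weights(c, rng)
            key = tuple(out.W[np.nonzero(A)])
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 6
        # multinomial: each of 6 permutations p=1/6, sd = sqrt(n p (1-p))
        expect = n / 6
        sd = np.sqrt(n * (1 / 6) * (5 / 6))
        for v in counts.values():
            assert abs(v - expect) < 3.5 * sd


class TestNormalizedMetric:
    def test_identity_ensemble_ratio_one(self, toy7):
        fn = lambda g: tn.clustering_binary(g).network_value
        ens = tn.build_ensemble(
            toy7, {"c": fn}, n_samples=20, seed=0, n_swaps=0
        )
        norm, p = tn.normalized_metric(toy7, fn, ens, name="c")
        assert norm == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_observed_above_all_nulls_reports_resolution_bound(self):
        null = np.zeros(200)
        assert tn.empirical_p(1.0, null) == pytest.approx(1 / 200)

    def test_small_graph_vs_exhaustive_swap_oracle(self):
        # 4-edge graph: enumerate the full closure of swap-reachable states
        # (the swap chain is symmetric, hence uniform over them) and compare
        # the sampled null mean of clustering against the exact closure mean.
        arcs0 = frozenset([(0, 1), (1, 2), (2, 0), (2, 3)])
        fn = lambda g: tn.clustering_binary(g).network_value

        def swap_neighbors(arcs):
            out = set()
            arcs = list(arcs)
            for x in range(len(arcs)):
                for y in range(len(arcs)):
                    if x == y:
                        continue
                    (a, b), (cc, d) = arcs[x], arcs[y]
                    if a == d or cc == b or b == d:
                        continue
                    if (a, d) in arcs or (cc, b) in arcs:
                        continue
                    new = set(arcs)
                    new -= {(a, b), (cc, d)}
                    new |= {(a, d), (cc, b)}
                    out.add(frozenset(new))
            return out

        seen = {arcs0}
        frontier = [arcs0]
        while frontier:
            nxt = []
            for st in frontier:
                for nb in swap_neighbors(st):
                    if nb not in seen:
                        seen.add(nb)
                        nxt.append(nb)
            frontier = nxt

        def as_conn(arcs):
            M = np.zeros((4, 4))
            for i, j in arcs:
                M[i, j] = 1
            return tn.Connectome(list("abcd"), M, M.astype(float), M.sum(axis=0))

        vals = [fn(as_conn(st)) for st in seen]
        assert len(seen) > 1 and np.std(vals) > 0  # nondegenerate oracle
        c = as_conn(arcs0)
        ens = tn.build_ensemble(c, {"c": fn}, n_samples=300, seed=3)
        assert ens.mean("c") == pytest.approx(np.mean(vals), abs=0.05)


class TestPermutationTest:
    def test_identical_groups_p_near_one(self, rng):
        a = [1.0, 1.0, 1.0]
        assert tn.permutation_test_groups(a, a, n_perm=200, rng=rng) == 1.0

    def test_disjoint_small_groups_match_exact_enumeration(self, rng):
        a, b = [10.0, 11.0, 12.0], [1.0, 2.0, 3.0]
        # exact two-sided p over all C(6,3)=20 assignments: only the observed
        # split and its mirror reach |diff| = 9 -> p = 2/20
        p = tn.permutation_test_groups(a, b, n_perm=20_000, rng=rng)
        assert p == pytest.approx(2 / 20, abs=0.01)

    def test_symmetric_in_group_order(self):
        a, b = [5.0, 6.0], [1.0, 2.0, 3.0]
        p1 = tn.permutation_test_groups(a, b, n_perm=2000, rng=np.random.default_rng(0))
        p2 = tn.permutation_test_groups(b, a, n_perm=2000, rng=np.random.default_rng(0))
        assert p1 == pytest.approx(p2, abs=0.02)

    def test_uniform_p_under_exchangeability(self):
        # label-permuted data: p-values should be roughly uniform
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(200):
            pooled = rng.normal(size=10)
            ps.append(tn.permutation_test_groups(pooled[:5], pooled[5:], n_perm=99, rng=rng))
        assert np.mean(ps) == pytest.approx(0.5, abs=0.08)


class TestFdrBH:
    def test_single_p_unchanged(self):
        adj, rej = tn.fdr_bh([0.03])
        assert adj[0] == pytest.approx(0.03)
        assert rej[0]

    def test_stepup_hand_computation(self):
        adj, _ = tn.fdr_bh([0.01, 0.02, 0.03, 0.04])
        # step-up: adjusted_i = min over j>=i of p_j * m / j = 0.04 for all
        assert np.allclose(adj, 0.04)

    def test_all_ones_no_rejections(self):
        _, rej = tn.fdr_bh([1.0, 1.0, 1.0])
        assert not rej.any()

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            tn.fdr_bh([0.5, 1.5])


class TestConservationBulk:
    def test_thousand_samples_conserve_everything(self):
        rng = np.random.default_rng(99)
        graphs = [random_connectome(rng, n=7, p=0.5) for _ in range(5)]
        for c in graphs:
            for _ in range(100):
                r = tn.rewire_preserving(c, rng=rng)
                assert np.array_equal(r.in_degree, c.in_degree)
                assert np.array_equal(r.out_degree, c.out_degree)
                assert np.allclose(r.in_strength, c.in_strength)
                s = tn.shuffle_weights(c, rng)
                assert np.array_equal(s.A, c.A)
                assert np.allclose(np.sort(s.W[s.A > 0]), np.sort(c.W[c.A > 0]))
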