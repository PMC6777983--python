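"""Independent brute-force oracles for the graph measures.

Everything here is written as plain loops over nodes/edges/pairs, without
reusing any package code path, so the fast implementations can be checked
against first principles on small graphs.
"""

import numpy as np


def clustering_directed_oracle(A, W=None):
    """Per-node directed clustering by ordered-triple enumeration.

    Counts every directed triangle motif through node i once (the "total"
    variant): t_i = 1/2 sum_{j != k} s_ij * s_jk * s_ki with
    s = cbrt(W) + cbrt(W)^T. Denominator from the binary graph:
    d_tot (d_tot - 1) - 2 d_bidir.
    """
    A = np.asarray(A)
    n = len(A)
    if W is None:
        W = A.astype(float)
    s = np.cbrt(np.asarray(W, dtype=float))
    out = np.zeros(n)
    for i in range(n):
        t = 0.0
        for j in range(n):
            for k in range(n):
                if j == i or k == i or j == k:
                    continue
                t += (s[i, j] + s[j, i]) * (s[j, k] + s[k, j]) * (s[k, i] + s[i, k])
        t /= 2.0
        d_tot = int(A[i].sum() + A[:, i].sum())
        d_bi = int((A[i] * A[:, i]).sum())
        denom = d_tot * (d_tot - 1) - 2 * d_bi
        out[i] = t / denom if denom > 0 else 0.0
    return out


def floyd_warshall_oracle(A):
    """All-pairs hop distance on a binary directed graph."""
    n = len(A)
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0)
    for i in range(n):
        for j in range(n):
            if i != j and A[i, j]:
                D[i, j] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def bellman_ford_lex_oracle(A, W):
    """All-pairs (min cost, min hops among min-cost) via edge relaxation.

    Cost of an edge is 1/w; lexicographic (cost, hops) order.
    """
    n = len(A)
    edges = [(i, j, 1.0 / W[i, j]) for i in range(n) for j in range(n) if A[i, j]]
    C = np.full((n, n), np.inf)
    H = np.full((n, n), np.inf)
    for s in range(n):
        C[s, s], H[s, s] = 0.0, 0
        for _ in range(2 * n * n):
            changed = False
            for i, j, cost in edges:
                if not np.isfinite(C[s, i]):
                    continue
                nc, nh = C[s, i] + cost, H[s, i] + 1
                if nc < C[s, j] - 1e-15 or (abs(nc - C[s, j]) <= 1e-15 and nh < H[s, j]):
                    C[s, j], H[s, j] = nc, nh
                    changed = True
            if not changed:
                break
    return C, H


def mean_off_diagonal(D):
    """Mean over finite off-diagonal entries."""
    n = len(D)
    vals = [D[i, j] for i in range(n) for j in range(n) if i != j and np.isfinite(D[i, j])]
    return float(np.mean(vals)) if vals else float("nan")


def phi_binary_oracle(A, k_in_ext, k):
    club = [i for i in range(len(A)) if k_in_ext[i] > k]
    if len(club) < 2:
        return float("nan")
    e = sum(int(A[i, j]) for i in club for j in club if i != j)
    return e / (len(club) * (len(club) - 1))


def phi_weighted_oracle(A, W, k_in_ext, k):
    n = len(A)
    club = [i for i in range(n) if k_in_ext[i] > k]
    if len(club) < 2:
        return float("nan")
    w_club = sum(W[i, j] for i in club for j in club if i != j and A[i, j])
    e_club = sum(int(A[i, j]) for i in club for j in club if i != j)
    if e_club == 0:
        return 0.0
    all_w = sorted((W[i, j] for i in range(n) for j in range(n) if A[i, j]), reverse=True)
    return w_club / sum(all_w[:e_club])


def modularity_oracle(M, assign):
    """Directed Q by explicit double sum over node pairs."""
    M = np.asarray(M, dtype=float)
    n = len(M)
    m = M.sum()
    k_out = M.sum(axis=1)
    k_in = M.sum(axis=0)
    q = 0.0
    for i in range(n):
        for j in range(n):
            if assign[i] == assign[j]:
                q += M[i, j] - k_out[i] * k_in[j] / m
    return q / m


def rand_index_oracle(a1, a2):
    """Pair-agreement fraction by explicit enumeration of node pairs."""
    n = len(a1)
    agree = total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += 1
            if (a1[i] == a1[j]) == (a2[i] == a2[j]):
                agree += 1
    return agree / total if total else 1.0


def pareto_oracle(points, maximize=(True, True)):
    """Nondominated mask by pairwise comparison in raw orientation."""
    pts = np.asarray(points, dtype=float)
    sign = np.array([1 if m else -1 for m in maximize])
    pts = pts * sign
    n = len(pts)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if np.all(pts[j] >= pts[i]) and np.any(pts[j] > pts[i]):
                mask[i] = False
                break
    return mask


def random_connectome(rng, n=None, p=None, weighted=True):
    """A random small directed weighted graph for oracle comparisons."""
    import tracenet as tn

    n = n if n is not None else int(rng.integers(3, 9))
    p = p if p is not None else rng.uniform(0.25, 0.9)
    while True:
        A = (rng.random((n, n)) < p).astype(np.int8)
        np.fill_diagonal(A, 0)
        if A.sum() >= 2:
            break
    W = np.zeros((n, n))
    W[A > 0] = rng.uniform(0.2, 5.0, size=int(A.sum())) if weighted else 1.0
    k_ext = A.sum(axis=0) + rng.integers(0, 4, size=n)
    return tn.Connectome(
        labels=[f"n{i}" for i in range(n)], A=A, W=W, k_in_ext=k_ext
    )
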