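"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written for clarity, not speed: Floyd-Warshall path
matrices, exhaustive triangle enumeration, explicit per-node loops.  These
functions must stay independent of the package's own metric code.
"""

import numpy as np


def floyd_warshall(adj):
    """Dense all-pairs shortest hop counts; np.inf when unreachable."""
    n = adj.shape[0]
    d = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def binary_metrics_oracle(adj):
    """d, L, C, Eglob, Eloc by exhaustive enumeration."""
    a = np.asarray(adj) > 0
    n = a.shape[0]
    e = a.sum() // 2
    density = 2 * e / (n * (n - 1))
    dist = floyd_warshall(a)

    tot = cnt = 0
    sinv = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(dist[i, j]):
                tot += dist[i, j]
                cnt += 1
                sinv += 1.0 / dist[i, j]
    L = tot / cnt if cnt else np.nan
    eglob = sinv / (n * (n - 1))

    C = 0.0
    for u in range(n):
        nbr = np.where(a[u])[0]
        k = len(nbr)
        if k < 2:
            continue
        t = 0
        for x in range(k):
            for y in range(x + 1, k):
                if a[nbr[x], nbr[y]]:
                    t += 1
        C += 2 * t / (k * (k - 1))
    C /= n

    eloc = 0.0
    for u in range(n):
        nbr = np.where(a[u])[0]
        k = len(nbr)
        if k < 2:
            continue
        sub = a[np.ix_(nbr, nbr)]
        dsub = floyd_warshall(sub)
        s = 0.0
        for i in range(k):
            for j in range(k):
                if i != j and np.isfinite(dsub[i, j]):
                    s += 1.0 / dsub[i, j]
        eloc += s / (k * (k - 1))
    eloc /= n
    return {"d": density, "L": L, "C": C, "Eglob": eglob, "Eloc": eloc}


def weighted_nodal_oracle(w):
    """S_i, E_i (costs 1/w), Onnela C_i by explicit loops."""
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    strength = w.sum(axis=1)

    cost = np.where(w > 0, 1.0 / np.where(w > 0, w, 1), np.inf)
    np.fill_diagonal(cost, 0.0)
    d = cost.copy()
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    eff = np.zeros(n)
    for i in range(n):
        s = 0.0
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                s += 1.0 / d[i, j]
        eff[i] = s / (n - 1) if n > 1 else 0.0

    wmax = w.max()
    what = w / wmax if wmax > 0 else w
    clus = np.zeros(n)
    for i in range(n):
        k = (w[i] > 0).sum()
        if k < 2:
            continue
        s = 0.0
        for j in range(n):
            for h in range(n):
                if j != i and h != i and j != h:
                    s += (what[i, j] * what[i, h] * what[j, h]) ** (1 / 3)
        clus[i] = s / (k * (k - 1))
    return strength, eff, clus


def random_symmetric(n, p, rng):
    a = (rng.random((n, n)) < p).astype(np.int8)
    a = np.triu(a, 1)
    return a + a.T
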