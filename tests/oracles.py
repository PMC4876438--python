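"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately naive (triple loops, exhaustive path
enumeration) and shares no code with the package's metric
implementations.
"""

from __future__ import annotations

import itertools

import numpy as np


def strength_oracle(w: np.ndarray) -> np.ndarray:
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            out[i] += w[i, j]
    return out


def clustering_oracle(w: np.ndarray) -> tuple[np.ndarray, float]:
    """Onnela max-rescaled geometric-mean clustering by triple loop.

    With 0/1 weights this equals 2*triangles/(k(k-1))."""
    n = w.shape[0]
    wmax = w.max()
    c = np.zeros(n)
    for i in range(n):
        k = int(np.count_nonzero(w[i]))
        if k < 2:
            continue
        acc = 0.0
        for j in range(n):
            for h in range(n):
                if j == i or h == i or j == h:
                    continue
                acc += (w[i, j] / wmax * w[j, h] / wmax * w[h, i] / wmax) ** (1 / 3)
        c[i] = acc / (k * (k - 1))
    return c, float(c.mean())


def floyd_warshall_oracle(w: np.ndarray) -> np.ndarray:
    """All-pairs distances with lengths 1/w, by dynamic programming."""
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def lp_oracle(w: np.ndarray) -> float:
    d = floyd_warshall_oracle(w)
    n = w.shape[0]
    vals = [d[i, j] for i in range(n) for j in range(n) if i != j]
    return float(np.mean(vals))


def efficiency_oracle(w: np.ndarray) -> np.ndarray:
    d = floyd_warshall_oracle(w)
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for j in range(n):
            if j != i and np.isfinite(d[i, j]):
                acc += 1.0 / d[i, j]
        out[i] = acc / (n - 1)
    return out


def betweenness_oracle(w: np.ndarray) -> np.ndarray:
    """Betweenness by exhaustive simple-path enumeration.

    Only usable on small graphs.  Fractional credit among degenerate
    shortest paths; normalized by (N-1)(N-2)/2."""
    n = w.shape[0]
    adj = {i: [j for j in range(n) if w[i, j] > 0] for i in range(n)}

    def all_simple_paths(s, t):
        paths = []
        stack = [(s, [s], 0.0)]
        while stack:
            node, path, length = stack.pop()
            if node == t:
                paths.append((path, length))
                continue
            for nxt in adj[node]:
                if nxt not in path:
                    stack.append((nxt, path + [nxt], length + 1.0 / w[node, nxt]))
        return paths

    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = all_simple_paths(s, t)
        if not paths:
            continue
        dmin = min(length for _, length in paths)
        shortest = [p for p, length in paths if length <= dmin * (1 + 1e-12)]
        for p in shortest:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(shortest)
    return bc / ((n - 1) * (n - 2) / 2)


def bh_stepup_oracle(pvals: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg step-up decisions by direct definition."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    kmax = 0
    for k in range(1, m + 1):
        if sorted_p[k - 1] <= k * alpha / m:
            kmax = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:kmax]] = True
    return reject


def trapezoid_oracle(x: np.ndarray, y: np.ndarray) -> float:
    acc = 0.0
    for i in range(len(x) - 1):
        acc += (x[i + 1] - x[i]) * (y[i] + y[i + 1]) / 2
    return acc


def spearman_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-free Spearman via the classical 1 - 6*sum(d^2)/(n(n^2-1))."""

    def ranks(v):
        order = np.argsort(v)
        r = np.empty(len(v))
        r[order] = np.arange(1, len(v) + 1)
        return r

    rx, ry = ranks(x), ranks(y)
    d = rx - ry
    n = len(x)
    return 1 - 6 * float(np.sum(d**2)) / (n * (n**2 - 1))


def connected_graphs_on(n: int):
    """Yield the edge sets of all connected labelled graphs on n nodes."""
    pairs = list(itertools.combinations(range(n), 2))
    for bits in range(1, 2 ** len(pairs)):
        edges = [pairs[i] for i in range(len(pairs)) if bits >> i & 1]
        # union-find connectivity
        parent = list(range(n))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for a, b in edges:
            parent[find(a)] = find(b)
        if len({find(i) for i in range(n)}) == 1:
            yield edges
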