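"""Degree- and weight-preserving random surrogates and the normalized
small-world measures gamma and lambda.

The surrogate for a weighted network is built in two steps that
together match the real network in node count, edge count, and exact
degree sequence while preserving its weight multiset:

1. Maslov-Sneppen rewiring of the binary topology (repeated double-edge
   swaps rejecting self-loops and multi-edges);
2. a random permutation of the real network's edge weights onto the
   rewired topology.

gamma = Cp / <Cp_random> and lambda = Lp / <Lp_random> over the
ensemble; a network is called small-world when gamma >> 1 while
lambda stays close to 1.  Surrogates that come out disconnected (so
Lp would be infinite) are regenerated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path as _sp_shortest_path

from wmnet.core import DisconnectedNetworkError, ThresholdedNetwork
from wmnet.metrics import global_metrics

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap

__all__ = [
    "NullEnsembleSummary",
    "rewire_preserving_degree",
    "assign_weights_preserving_distribution",
    "normalized_small_world",
    "is_small_world",
]


@dataclass(frozen=True)
class NullEnsembleSummary:
    """Ensemble means of surrogate metrics and the normalized ratios."""

    n_random: int
    cp: float
    lp: float
    c_random: float
    l_random: float
    c_random_sd: float
    l_random_sd: float
    gamma: float
    lambda_: float
    seed: int | None


@njit(cache=True)
def _swap_kernel(adj, edges, e1, e2, flip, n_target):  # pragma: no cover - jitted
    successes = 0
    for t in range(e1.size):
        if successes >= n_target:
            break
        p = e1[t]
        q = e2[t]
        if p == q:
            continue
        a = edges[p, 0]
        b = edges[p, 1]
        c = edges[q, 0]
        d = edges[q, 1]
        if flip[t]:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = False
        adj[b, a] = False
        adj[c, d] = False
        adj[d, c] = False
        adj[a, d] = True
        adj[d, a] = True
        adj[c, b] = True
        adj[b, c] = True
        edges[p, 1] = d
        edges[q, 0] = c
        edges[q, 1] = b
        successes += 1
    return successes


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def _rewire_edges(adj: np.ndarray, edges: np.ndarray, n_swaps: int,
                  rng: np.random.Generator) -> None:
    """In-place Maslov-Sneppen double-edge swaps on (adj, edges).

    Performs up to ``n_swaps`` successful swaps; gives up early on
    rigid graphs (no valid swap found over a long streak of attempts).
    """
    m = edges.shape[0]
    if m < 2:
        return
    remaining = int(n_swaps)
    budget = max(50 * int(n_swaps), 1000)
    while remaining > 0 and budget > 0:
        chunk = min(budget, max(2 * remaining, 256))
        e1 = rng.integers(0, m, size=chunk)
        e2 = rng.integers(0, m, size=chunk)
        flip = rng.integers(0, 2, size=chunk).astype(np.bool_)
        done = _swap_kernel(adj, edges, e1, e2, flip, remaining)
        remaining -= int(done)
        budget -= chunk
        if done == 0 and chunk >= 50 * m:
            break  # no valid swap found in a long streak: rigid graph


def _cp_lp_fast(w: np.ndarray) -> tuple[float, float]:
    """(Cp, Lp) from a dense weight matrix; Lp is inf if disconnected.

    Same conventions as :mod:`wmnet.metrics`: max-rescaled Onnela
    clustering and shortest paths on the 1/w length graph.
    """
    n = w.shape[0]
    a = w > 0
    k = a.sum(axis=1)
    wmax = w.max()
    if wmax == 0:
        return 0.0, np.inf
    w13 = np.cbrt(w / wmax)
    num = ((w13 @ w13) * w13).sum(axis=1)  # diag of W13^3 (symmetric W13)
    denom = k * (k - 1)
    c = np.where(denom > 0, num / np.where(denom > 0, denom, 1), 0.0)
    lengths = np.zeros_like(w)
    lengths[a] = 1.0 / w[a]
    d = _sp_shortest_path(lengths, method="FW", directed=False)
    off = d[~np.eye(n, dtype=bool)]
    return float(c.mean()), float(off.mean())  # mean propagates inf


def rewire_preserving_degree(t: ThresholdedNetwork, n_swaps: int | None = None,
                             rng_seed=None) -> ThresholdedNetwork:
    """Randomize the binary topology by double-edge swaps.

    Performs ``n_swaps`` successful swaps (default 10 x edge count),
    each rejecting self-loops and multi-edges, so the degree sequence
    is preserved exactly.  Rigid graphs that admit no valid swap (e.g.
    a triangle) are returned unchanged once the attempt budget is
    spent.  The result is a binary network; weights are re-imposed
    separately with :func:`assign_weights_preserving_distribution`.
    """
    rng = _as_rng(rng_seed)
    adj = (t.weights > 0).copy()
    iu, ju = np.nonzero(np.triu(adj, 1))
    edges = np.stack([iu, ju], axis=1).astype(np.int64)
    if n_swaps is None:
        n_swaps = 10 * edges.shape[0]
    _rewire_edges(adj, edges, n_swaps, rng)
    out = np.zeros_like(t.weights)
    out[edges[:, 0], edges[:, 1]] = 1.0
    out = out + out.T
    return ThresholdedNetwork(weights=out, sparsity=t.sparsity, binary=True,
                              subject_id=t.subject_id)


def assign_weights_preserving_distribution(topology: ThresholdedNetwork,
                                           source: ThresholdedNetwork,
                                           rng_seed=None) -> ThresholdedNetwork:
    """Permute the source's edge-weight multiset onto a topology.

    The topology and the source must have the same edge count; the
    sorted weight multiset of the output equals the source's exactly.
    """
    rng = _as_rng(rng_seed)
    ti, tj = np.nonzero(np.triu(topology.weights, 1))
    si, sj = np.nonzero(np.triu(source.weights, 1))
    if ti.size != si.size:
        raise ValueError(
            f"edge-count mismatch: topology {ti.size} vs source {si.size}"
        )
    w_src = source.weights[si, sj]
    perm = rng.permutation(w_src.size)
    out = np.zeros_like(source.weights)
    out[ti, tj] = w_src[perm]
    out = out + out.T
    return ThresholdedNetwork(weights=out, sparsity=source.sparsity,
                              binary=source.binary, subject_id=source.subject_id)


def normalized_small_world(t: ThresholdedNetwork, n_random: int = 1000,
                           rng_seed=None, swap_factor: int = 10,
                           max_regen: int = 200) -> NullEnsembleSummary:
    """Normalize Cp and Lp of a connected network against surrogates.

    Builds ``n_random`` rewired + weight-permuted surrogates from a
    single random stream, averaging their Cp and Lp; disconnected
    surrogates are regenerated (up to ``max_regen`` attempts each).
    Returns gamma = Cp/C_random and lambda = Lp/L_random.  With a
    fixed seed the summary is bit-identical across runs.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    cp, lp = global_metrics(t)
    w = t.weights
    adj0 = w > 0
    iu, ju = np.nonzero(np.triu(adj0, 1))
    base_edges = np.stack([iu, ju], axis=1).astype(np.int64)
    w_src = w[iu, ju]
    m = base_edges.shape[0]
    n_swaps = swap_factor * m
    rng = _as_rng(rng_seed if not isinstance(rng_seed, np.random.Generator)
                  else rng_seed)
    cs = np.empty(n_random)
    ls = np.empty(n_random)
    for i in range(n_random):
        for _ in range(max_regen):
            adj = adj0.copy()
            edges = base_edges.copy()
            _rewire_edges(adj, edges, n_swaps, rng)
            sur = np.zeros_like(w)
            if t.binary:
                sur[edges[:, 0], edges[:, 1]] = 1.0
            else:
                sur[edges[:, 0], edges[:, 1]] = w_src[rng.permutation(m)]
            sur = sur + sur.T
            ci, li = _cp_lp_fast(sur)
            if np.isfinite(li):
                cs[i], ls[i] = ci, li
                break
        else:
            raise DisconnectedNetworkError(
                "could not generate a connected surrogate"
            )
    c_random = float(cs.mean())
    l_random = float(ls.mean())
    return NullEnsembleSummary(
        n_random=n_random,
        cp=cp,
        lp=lp,
        c_random=c_random,
        l_random=l_random,
        c_random_sd=float(cs.std(ddof=1)) if n_random > 1 else 0.0,
        l_random_sd=float(ls.std(ddof=1)) if n_random > 1 else 0.0,
        gamma=cp / c_random,
        lambda_=lp / l_random,
        seed=None if rng_seed is None or isinstance(rng_seed, np.random.Generator)
        else int(rng_seed),
    )


def is_small_world(s: NullEnsembleSummary, gamma_min: float = 1.5,
                   lambda_tol: float = 0.5) -> bool:
    """Small-world verdict: gamma >= gamma_min and lambda within
    [1 - lambda_tol, 1 + lambda_tol].  Thresholds are configuration and
    should be reported alongside the verdict."""
    return bool(s.gamma >= gamma_min
                and (1.0 - lambda_tol) <= s.lambda_ <= (1.0 + lambda_tol))
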