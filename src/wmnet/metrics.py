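"""Global and nodal graph metrics for thresholded networks.

Conventions
-----------
* Edge *length* is the reciprocal of edge weight, l_ij = 1/w_ij (1 for
  binary networks): stronger connections are shorter.  Shortest paths
  are exact (Dijkstra on the length graph).
* Weighted clustering uses the Onnela geometric-mean triangle formula
  with weights rescaled by the network maximum, so it reduces exactly
  to the binary clustering coefficient when all weights are equal and
  is invariant under uniform rescaling of the weights.
* The characteristic path length Lp averages distances over all
  ordered pairs and requires a fully connected network; a disconnected
  input raises :class:`DisconnectedNetworkError` rather than silently
  switching to a harmonic mean.
* Nodal betweenness is normalized by (N-1)(N-2)/2, with fractional
  credit shared among degenerate shortest paths.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _sp_shortest_path

from wmnet.core import DisconnectedNetworkError, ThresholdedNetwork

__all__ = [
    "nodal_strength",
    "clustering_coefficient",
    "shortest_path_matrix",
    "characteristic_path_length",
    "nodal_efficiency",
    "nodal_betweenness",
]


def nodal_strength(t: ThresholdedNetwork) -> np.ndarray:
    """Sum of the weights of all edges incident to each node."""
    return t.weights.sum(axis=1)


def _clustering_from_weights(w: np.ndarray) -> tuple[np.ndarray, float]:
    # Onnela: C_i = sum_{j,h} (ŵ_ij ŵ_jh ŵ_hi)^(1/3) / (k_i (k_i - 1)),
    # ŵ = w / max(w).  With 0/1 weights this is 2·triangles/(k(k-1)).
    a = (w > 0)
    k = a.sum(axis=1)
    wmax = w.max()
    if wmax == 0:
        return np.zeros(w.shape[0]), 0.0
    w13 = np.cbrt(w / wmax)
    num = np.einsum("ij,jh,hi->i", w13, w13, w13)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, num / np.where(denom > 0, denom, 1), 0.0)
    return c, float(c.mean())


def clustering_coefficient(t: ThresholdedNetwork) -> tuple[np.ndarray, float]:
    """Per-node clustering coefficients and their mean Cp.

    Binary networks use the triangle-density formula
    C_i = 2 t_i / (k_i (k_i - 1)); weighted networks the max-rescaled
    Onnela geometric-mean form.  Nodes with degree < 2 get C_i = 0.
    """
    return _clustering_from_weights(t.weights)


def _length_graph(w: np.ndarray) -> csr_matrix:
    n = w.shape[0]
    i, j = np.nonzero(np.triu(w, 1))
    lengths = 1.0 / w[i, j]
    g = csr_matrix((lengths, (i, j)), shape=(n, n))
    return g


def shortest_path_matrix(t: ThresholdedNetwork) -> np.ndarray:
    """All-pairs shortest-path distances on the l = 1/w length graph.

    Disconnected pairs are reported as ``inf``.
    """
    return _distance_matrix(t.weights)


def _distance_matrix(w: np.ndarray) -> np.ndarray:
    return _sp_shortest_path(_length_graph(w), method="D", directed=False)


def characteristic_path_length(t: ThresholdedNetwork) -> float:
    """Mean shortest-path distance over all ordered pairs i != j.

    Raises :class:`DisconnectedNetworkError` if any pair is unreachable.
    """
    return _lp_from_distances(_distance_matrix(t.weights))


def _lp_from_distances(d: np.ndarray) -> float:
    n = d.shape[0]
    off = d[~np.eye(n, dtype=bool)]
    if np.any(np.isinf(off)):
        raise DisconnectedNetworkError("disconnected network: Lp undefined")
    return float(off.mean())


def nodal_efficiency(t: ThresholdedNetwork) -> np.ndarray:
    """E(i) = mean over j != i of 1/d(i, j); unreachable pairs add 0."""
    d = _distance_matrix(t.weights)
    n = d.shape[0]
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def nodal_betweenness(t: ThresholdedNetwork) -> np.ndarray:
    """Shortest-path betweenness centrality on the 1/w length graph.

    Normalized by (N-1)(N-2)/2; degenerate shortest paths share credit
    fractionally (Brandes' algorithm).
    """
    w = t.weights
    n = w.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    i, j = np.nonzero(np.triu(w, 1))
    g.add_weighted_edges_from(
        zip(i.tolist(), j.tolist(), (1.0 / w[i, j]).tolist()), weight="length"
    )
    bc = nx.betweenness_centrality(g, weight="length", normalized=True)
    return np.array([bc[v] for v in range(n)])


def global_metrics(t: ThresholdedNetwork) -> tuple[float, float]:
    """(Cp, Lp) of a thresholded network."""
    _, cp = clustering_coefficient(t)
    lp = characteristic_path_length(t)
    return cp, lp


def _cp_lp_from_weights(w: np.ndarray) -> tuple[float, float]:
    # fast path used by the null-ensemble loop (no dataclass validation)
    _, cp = _clustering_from_weights(w)
    return cp, _lp_from_distances(_distance_matrix(w))
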