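"""Node centrality for weighted symptom networks.

Undirected networks get strength, closeness and betweenness; directed
(cross-lagged) networks get in- and out-strength.  Distances for the
path-based indices use the standard psychological-network convention:
the length of an edge is the inverse of its absolute weight, so strong
edges are short.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "strength",
    "shortest_path_lengths",
    "closeness",
    "betweenness",
    "directed_strength",
    "standardize",
    "centrality_table",
    "directed_centrality_table",
]


def _check_symmetric(W) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(W, W.T):
        raise ValueError("weight matrix must be symmetric")
    return W


def _graph(W: np.ndarray) -> nx.Graph:
    """Graph over all nodes with edge attribute length = 1/|weight|."""
    p = W.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(p))
    for i in range(p):
        for j in range(i + 1, p):
            if W[i, j] != 0:
                G.add_edge(i, j, length=1.0 / abs(W[i, j]))
    return G


def strength(W) -> np.ndarray:
    """Node strength: the sum of absolute incident edge weights."""
    W = _check_symmetric(W)
    return np.abs(W).sum(axis=1)


def shortest_path_lengths(W) -> np.ndarray:
    """All-pairs shortest path distances over edge lengths 1/|weight|.

    Unreachable pairs are +inf; the diagonal is 0.
    """
    W = _check_symmetric(W)
    p = W.shape[0]
    G = _graph(W)
    D = np.full((p, p), np.inf)
    np.fill_diagonal(D, 0.0)
    for src, lengths in nx.all_pairs_dijkstra_path_length(G, weight="length"):
        for dst, d in lengths.items():
            D[src, dst] = d
    return D


def closeness(W, variant: str = "inverse_sum") -> np.ndarray:
    """Closeness centrality of each node.

    - ``inverse_sum`` (default, the convention of standard network
      software): 1 / sum of distances to the other nodes, summed over
      the node's reachable component only so the index stays finite in
      sparse networks.
    - ``harmonic``: sum of inverse distances (unreachable contribute 0).

    Isolated nodes get closeness 0 under both variants.
    """
    if variant not in ("inverse_sum", "harmonic"):
        raise ValueError("variant must be 'inverse_sum' or 'harmonic'")
    D = shortest_path_lengths(W)
    p = D.shape[0]
    out = np.zeros(p)
    for i in range(p):
        d = np.delete(D[i], i)
        reach = np.isfinite(d) & (d > 0)
        if variant == "harmonic":
            out[i] = float(np.sum(1.0 / d[reach])) if reach.any() else 0.0
        else:
            out[i] = float(1.0 / d[reach].sum()) if reach.any() else 0.0
    return out


def betweenness(W) -> np.ndarray:
    """Weighted betweenness: for each unordered pair (s, t) of other
    nodes, the fraction of shortest s-t paths through the node, summed
    over pairs (unnormalized)."""
    W = _check_symmetric(W)
    G = _graph(W)
    bc = nx.betweenness_centrality(G, weight="length", normalized=False)
    return np.array([bc[i] for i in range(W.shape[0])])


def directed_strength(B, include_self: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """In- and out-strength of a directed coefficient matrix.

    ``B[j, k]`` is the effect of node j on node k, so
    out_j = sum_k |B[j, k]| and in_k = sum_j |B[j, k]|; the diagonal
    (autoregressive self-loops) is excluded unless ``include_self``.
    Returns ``(in_strength, out_strength)``.
    """
    B = np.asarray(B, dtype=float)
    if B.ndim != 2 or B.shape[0] != B.shape[1]:
        raise ValueError("directed matrix must be square")
    A = np.abs(B)
    if not include_self:
        A = A - np.diag(np.diag(A))
    return A.sum(axis=0), A.sum(axis=1)


def standardize(values) -> np.ndarray:
    """z-scores across nodes with sample (n-1) SD; a constant vector
    returns all zeros with a warning."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to standardize")
    sd = v.std(ddof=1)
    if sd == 0:
        logger.warning("constant centrality vector; z-scores set to 0")
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def centrality_table(W, labels=None, closeness_variant: str = "inverse_sum") -> pd.DataFrame:
    """Raw and standardized strength/closeness/betweenness per node of an
    undirected weighted network."""
    W = _check_symmetric(W)
    p = W.shape[0]
    labels = list(labels) if labels is not None else [f"item{i+1}" for i in range(p)]
    s = strength(W)
    c = closeness(W, closeness_variant)
    b = betweenness(W)
    return pd.DataFrame({
        "node": labels,
        "strength": s, "strength_z": standardize(s),
        "closeness": c, "closeness_z": standardize(c),
        "betweenness": b, "betweenness_z": standardize(b),
        "closeness_variant": closeness_variant,
    })


def directed_centrality_table(B, labels=None, include_self: bool = False) -> pd.DataFrame:
    """Raw and standardized in-/out-strength per node of a directed
    (cross-lagged) network."""
    B = np.asarray(B, dtype=float)
    p = B.shape[0]
    labels = list(labels) if labels is not None else [f"item{i+1}" for i in range(p)]
    instr, outstr = directed_strength(B, include_self)
    return pd.DataFrame({
        "node": labels,
        "in_strength": instr, "in_strength_z": standardize(instr),
        "out_strength": outstr, "out_strength_z": standardize(outstr),
        "includes_autoregressive": include_self,
    })
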