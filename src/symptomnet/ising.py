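"""Cross-sectional Ising network estimation (the eLasso procedure).

Each symptom is regressed on all others with L1-penalized logistic
regression; the extended Bayesian information criterion (EBIC) selects
the penalty per node; the node-wise coefficients are then assembled into
a single undirected network, by default under the conservative AND rule
(an edge survives only if both of its directed coefficients are
non-zero).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._l1logistic import CoefficientPath, fit_lasso_path

logger = logging.getLogger(__name__)

__all__ = [
    "IsingNetwork",
    "lasso_logistic_path",
    "ebic",
    "select_ebic",
    "fit_elasso_node",
    "combine_rule",
    "estimate_ising",
]


def lasso_logistic_path(y, X, lambdas=None, *, n_lambda: int = 100,
                        min_ratio: float = 1e-3, tol: float = 1e-9) -> CoefficientPath:
    """L1 logistic path of one node on its potential neighbours.

    Minimizes -loglik + lam * n * ||beta||_1 (intercept unpenalized) at
    each lambda of a decreasing grid; see
    :func:`symptomnet._l1logistic.fit_lasso_path`.  Predictors are used
    raw (binary), so coefficients live on the log-odds coupling scale.
    """
    return fit_lasso_path(X, y, lambdas, n_lambda=n_lambda,
                          min_ratio=min_ratio, standardize=False, tol=tol)


def ebic(loglik: float, k: int, n: int, p_neighbors: int, gamma: float = 0.25) -> float:
    """Extended BIC: -2*loglik + k*log(n) + 2*gamma*k*log(p_neighbors).

    ``k`` is the number of non-zero slopes and ``p_neighbors`` the number
    of candidate predictors; gamma = 0 reduces to the ordinary BIC term
    structure, larger gamma prefers sparser models.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if n < 1:
        raise ValueError("n must be >= 1")
    extra = 2.0 * gamma * k * np.log(p_neighbors) if k > 0 else 0.0
    return float(-2.0 * loglik + k * np.log(n) + extra)


def select_ebic(path: CoefficientPath, n: int, p_neighbors: int,
                gamma: float = 0.25) -> int:
    """Index of the EBIC-minimizing lambda; ties resolve to the larger
    lambda (the sparser model)."""
    scores = np.array([ebic(path.loglik[i], int(path.nonzero[i]), n,
                            p_neighbors, gamma)
                       for i in range(path.lambdas.size)])
    # grid is decreasing in lambda: the first strict minimum wins ties
    return int(np.argmin(scores))


@dataclass
class NodeFit:
    """Selected node-wise regression: intercept + coefficients on the
    other nodes (in original node order, skipping the node itself)."""

    intercept: float
    coefficients: np.ndarray
    selected_lambda: float
    selected_index: int
    degenerate: bool = False


def fit_elasso_node(node: int, data: np.ndarray, gamma: float = 0.25,
                    *, n_lambda: int = 100, min_ratio: float = 1e-3,
                    tol: float = 1e-9) -> NodeFit:
    """EBIC-selected L1 logistic regression of one node on all others.

    A degenerate node (all 0 or all 1 — likely for rare symptoms at
    small n) yields an all-zero fit with a logged warning instead of an
    error, so network estimation can proceed.
    """
    data = np.asarray(data)
    n, p = data.shape
    y = data[:, node].astype(float)
    if y.min() == y.max():
        logger.warning("node %d is degenerate (constant %d); "
                       "returning an empty model", node, int(y[0]))
        return NodeFit(np.inf if y[0] == 1 else -np.inf,
                       np.zeros(p - 1), np.nan, -1, degenerate=True)
    X = np.delete(data, node, axis=1).astype(float)
    path = lasso_logistic_path(y, X, n_lambda=n_lambda,
                               min_ratio=min_ratio, tol=tol)
    k = select_ebic(path, n, p - 1, gamma)
    return NodeFit(float(path.intercepts[k]), path.coefs[k].copy(),
                   float(path.lambdas[k]), k)


def combine_rule(directed: np.ndarray, rule: str = "AND") -> np.ndarray:
    """Assemble a symmetric weight matrix from node-wise coefficients.

    ``directed[i, j]`` is the coefficient of predictor j in the
    regression of node i.  AND: the edge is the mean of the two directed
    coefficients if both are non-zero, else 0.  OR: the mean of the
    non-zero coefficients if at least one is non-zero.
    """
    directed = np.asarray(directed, dtype=float)
    p = directed.shape[0]
    W = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            a, b = directed[i, j], directed[j, i]
            if rule == "AND":
                w = (a + b) / 2.0 if (a != 0.0 and b != 0.0) else 0.0
            elif rule == "OR":
                nz = [v for v in (a, b) if v != 0.0]
                w = float(np.mean(nz)) if nz else 0.0
            else:
                raise ValueError("rule must be 'AND' or 'OR'")
            W[i, j] = W[j, i] = w
    return W


@dataclass
class IsingNetwork:
    """Estimated undirected symptom network.

    ``weights`` is symmetric with zero diagonal; ``directed`` keeps the
    underlying node-wise coefficients (row i = regression of node i)
    for diagnostics.
    """

    labels: tuple
    thresholds: np.ndarray
    weights: np.ndarray
    directed: np.ndarray
    gamma: float
    rule: str
    selected_lambdas: np.ndarray
    degenerate_nodes: tuple = ()
    meta: dict = field(default_factory=dict)

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    def edge_list(self) -> pd.DataFrame:
        """Long-format upper-triangle edge list (all possible edges)."""
        rows = []
        for i in range(self.p):
            for j in range(i + 1, self.p):
                rows.append({"node_i": self.labels[i], "node_j": self.labels[j],
                             "weight": self.weights[i, j]})
        return pd.DataFrame(rows)

    def n_possible_edges(self) -> int:
        return self.p * (self.p - 1) // 2

    def nonzero_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def mean_nonzero_weight(self) -> float:
        w = np.triu(self.weights, 1)
        nz = w[w != 0]
        return float(nz.mean()) if nz.size else np.nan

    # -- export ---------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "labels": list(self.labels),
            "thresholds": self.thresholds.tolist(),
            "weights": self.weights.tolist(),
            "gamma": self.gamma, "rule": self.rule,
            "selected_lambdas": self.selected_lambdas.tolist(),
            "degenerate_nodes": list(self.degenerate_nodes),
            "meta": self.meta,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def to_graphml(self, path: str | Path) -> None:
        import networkx as nx
        G = nx.Graph()
        for i, lab in enumerate(self.labels):
            G.add_node(lab, threshold=float(self.thresholds[i]))
        for i in range(self.p):
            for j in range(i + 1, self.p):
                if self.weights[i, j] != 0:
                    G.add_edge(self.labels[i], self.labels[j],
                               weight=float(self.weights[i, j]))
        nx.write_graphml(G, path)


def estimate_ising(data, gamma: float = 0.25, rule: str = "AND", *,
                   labels=None, n_lambda: int = 100, min_ratio: float = 1e-3,
                   tol: float = 1e-9) -> IsingNetwork:
    """Estimate the Ising symptom network by node-wise EBIC-LASSO.

    Parameters
    ----------
    data : (n, p) binary matrix of complete cases.
    gamma : EBIC sparsity hyperparameter (0.25 is the conventional
        choice for symptom networks).
    rule : "AND" (conservative, default) or "OR" edge assembly.

    Degenerate nodes are retained with all-zero rows/columns and listed
    in ``degenerate_nodes``.
    """
    data = np.asarray(data)
    if data.ndim != 2 or data.shape[0] < 3:
        raise ValueError("data must be (n >= 3, p) binary")
    if not np.all((data == 0) | (data == 1)):
        raise ValueError("data must be 0/1; dichotomize first")
    n, p = data.shape
    if labels is None:
        labels = tuple(f"item{i+1}" for i in range(p))
    directed = np.zeros((p, p))
    thresholds = np.empty(p)
    sel = np.full(p, np.nan)
    degenerate = []
    for i in range(p):
        fit = fit_elasso_node(i, data, gamma, n_lambda=n_lambda,
                              min_ratio=min_ratio, tol=tol)
        if fit.degenerate:
            degenerate.append(i)
        thresholds[i] = fit.intercept
        sel[i] = fit.selected_lambda
        directed[i, np.arange(p) != i] = fit.coefficients
    W = combine_rule(directed, rule)
    return IsingNetwork(tuple(labels), thresholds, W, directed, gamma, rule,
                        sel, tuple(degenerate),
                        meta={"n": n, "n_lambda": n_lambda,
                              "lambda_min_ratio": min_ratio})
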