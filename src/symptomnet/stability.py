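"""Bootstrap accuracy and stability diagnostics for estimated networks.

Three procedures, all non-parametric over persons:

- accuracy: percentile confidence intervals for edge weights from
  resampling persons with replacement;
- difference tests: for each pair of edges (or of node centralities),
  the bootstrap distribution of their difference — a pair differs
  "significantly" when the central 95% interval excludes zero;
- correlation-stability (CS): the case-dropping subset bootstrap — drop
  a growing proportion of persons, re-estimate, correlate the subset
  centralities with the full-sample ones; the CS coefficient is the
  largest drop proportion at which at least 95% of subsets keep a
  correlation of at least 0.70.

Estimators are passed as callables mapping a person-row data array to a
named parameter vector, so the same machinery serves the undirected
Ising network and the directed cross-lagged network.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .centrality import betweenness, closeness, strength, directed_strength
from .clpn import estimate_clpn
from .ising import estimate_ising

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeBootstrap",
    "DifferenceTests",
    "CaseDroppingResult",
    "StabilityReport",
    "ising_edge_fn",
    "ising_centrality_fn",
    "clpn_edge_fn",
    "clpn_centrality_fn",
    "bootstrap_edges",
    "difference_tests",
    "case_dropping_cs",
    "DEFAULT_DROP_PROPORTIONS",
]

DEFAULT_DROP_PROPORTIONS = tuple(np.round(np.arange(0.10, 0.751, 0.05), 2))


# ---------------------------------------------------------------------------
# Estimator adapters: data (n, ...) -> (names, parameter vector)
# ---------------------------------------------------------------------------

def ising_edge_fn(gamma: float = 0.25, rule: str = "AND", **kw):
    """Upper-triangle edge weights of the Ising network, as a vector."""
    def fit(data):
        net = estimate_ising(data, gamma, rule, **kw)
        iu = np.triu_indices(net.p, 1)
        names = [f"{i}--{j}" for i, j in zip(*iu)]
        return names, net.weights[iu]
    return fit


def ising_centrality_fn(index: str = "strength", gamma: float = 0.25,
                        rule: str = "AND", closeness_variant: str = "inverse_sum",
                        **kw):
    """Node centralities of the Ising network, as a vector."""
    fns = {"strength": strength,
           "closeness": lambda W: closeness(W, closeness_variant),
           "betweenness": betweenness}
    if index not in fns:
        raise ValueError(f"unknown centrality index {index!r}")
    def fit(data):
        net = estimate_ising(data, gamma, rule, **kw)
        names = [f"node{i}" for i in range(net.p)]
        return names, fns[index](net.weights)
    return fit


def clpn_edge_fn(folds: int = 10, seed: int = 0, **kw):
    """All p*p directed coefficients of the CLPN, as a vector.

    ``seed`` fixes the CV fold assignment inside each refit so the
    bootstrap varies only the resampled persons.
    """
    def fit(data):
        net = estimate_clpn(data, folds=folds, seed=seed, **kw)
        p = net.p
        names = [f"{j}->{k}" for j in range(p) for k in range(p)]
        return names, net.matrix.ravel()
    return fit


def clpn_centrality_fn(index: str = "out_strength", folds: int = 10,
                       seed: int = 0, include_self: bool = False, **kw):
    if index not in ("in_strength", "out_strength"):
        raise ValueError(f"unknown directed centrality {index!r}")
    def fit(data):
        net = estimate_clpn(data, folds=folds, seed=seed, **kw)
        instr, outstr = directed_strength(net.matrix, include_self)
        names = [f"node{i}" for i in range(net.p)]
        return names, (instr if index == "in_strength" else outstr)
    return fit


# ---------------------------------------------------------------------------
# Procedures
# ---------------------------------------------------------------------------

@dataclass
class EdgeBootstrap:
    names: list
    sample_estimate: np.ndarray
    boot_mean: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_boot: int
    seed: int | None
    replicates: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": self.names, "estimate": self.sample_estimate,
            "boot_mean": self.boot_mean, "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
        })


def _resample_rows(data, rng):
    n = data.shape[0]
    return data[rng.integers(n, size=n)]


def _bootstrap_params(data, fit, B, rng):
    names, est = fit(data)
    reps = np.empty((B, est.size))
    for b in range(B):
        reps[b] = fit(_resample_rows(data, rng))[1]
    return names, est, reps


def bootstrap_edges(data, fit, B: int = 1000, seed=None,
                    keep_replicates: bool = False) -> EdgeBootstrap:
    """Percentile bootstrap CIs (2.5/97.5) for network parameters.

    ``fit`` maps a person-row array to (names, parameter vector); the
    sample estimate is reported alongside the interval.  B = 1 is
    permitted (degenerate interval) with a warning.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if B == 1:
        logger.warning("B=1 gives a degenerate bootstrap interval")
    data = np.asarray(data)
    rng = np.random.default_rng(seed)
    names, est, reps = _bootstrap_params(data, fit, B, rng)
    lo, hi = np.percentile(reps, [2.5, 97.5], axis=0)
    return EdgeBootstrap(names, est, reps.mean(axis=0), lo, hi, B,
                         seed if isinstance(seed, int) else None,
                         reps if keep_replicates else None)


@dataclass
class DifferenceTests:
    names: list
    significant: np.ndarray       # symmetric boolean matrix
    ci_lower: np.ndarray          # pairwise difference CI bounds
    ci_upper: np.ndarray
    n_boot: int
    seed: int | None


def difference_tests(data, fit, B: int = 1000, seed=None) -> DifferenceTests:
    """Bootstrapped difference tests between all pairs of parameters.

    Parameters i, j differ significantly when the 95% percentile CI of
    the bootstrap distribution of (theta_i - theta_j) excludes zero.
    The resulting matrix is symmetric with a False diagonal.
    """
    data = np.asarray(data)
    rng = np.random.default_rng(seed)
    names, est, reps = _bootstrap_params(data, fit, B, rng)
    m = est.size
    diff = reps[:, :, None] - reps[:, None, :]      # (B, m, m)
    lo, hi = np.percentile(diff, [2.5, 97.5], axis=0)
    sig = (lo > 0) | (hi < 0)
    np.fill_diagonal(sig, False)
    return DifferenceTests(names, sig, lo, hi, B,
                           seed if isinstance(seed, int) else None)


@dataclass
class CaseDroppingResult:
    proportions: np.ndarray
    correlations: np.ndarray      # (n_props, B) subset-to-full correlations
    prop_above: np.ndarray        # fraction of subsets with r >= threshold
    cs_coefficient: float
    r_threshold: float
    prob: float
    n_boot: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "drop_proportion": self.proportions,
            "prop_correlations_above": self.prop_above,
            "mean_correlation": np.nanmean(self.correlations, axis=1),
        })


def case_dropping_cs(data, fit, proportions=DEFAULT_DROP_PROPORTIONS,
                     B: int = 1000, seed=None, r_threshold: float = 0.70,
                     prob: float = 0.95, use_spearman: bool = False) -> CaseDroppingResult:
    """Case-dropping subset bootstrap and the CS coefficient.

    For each drop proportion q, draws B subsets of (1-q)*n persons
    without replacement, re-estimates the centralities, and correlates
    them (Pearson by default) with the full-sample centralities.
    CS = the largest q at which at least ``prob`` of subsets reach a
    correlation of at least ``r_threshold``; 0.0 if none does.
    Undefined correlations (constant vectors) count as below threshold.
    """
    data = np.asarray(data)
    n = data.shape[0]
    rng = np.random.default_rng(seed)
    _, full = fit(data)
    props = np.asarray(proportions, dtype=float)
    cors = np.full((props.size, B), np.nan)
    n_undefined = 0
    for qi, q in enumerate(props):
        keep = max(3, int(round((1.0 - q) * n)))
        for b in range(B):
            idx = rng.choice(n, size=keep, replace=False)
            _, sub = fit(data[idx])
            if np.std(sub) == 0 or np.std(full) == 0:
                n_undefined += 1
                continue   # stays NaN -> counted below threshold
            if use_spearman:
                from scipy.stats import spearmanr
                cors[qi, b] = spearmanr(full, sub).statistic
            else:
                cors[qi, b] = np.corrcoef(full, sub)[0, 1]
    if n_undefined:
        logger.info("%d subsets had constant centralities; counted as "
                    "below the correlation threshold", n_undefined)
    with np.errstate(invalid="ignore"):
        above = np.where(np.isnan(cors), False, cors >= r_threshold)
    prop_above = above.mean(axis=1)
    qualifying = props[prop_above >= prob]
    cs = float(qualifying.max()) if qualifying.size else 0.0
    return CaseDroppingResult(props, cors, prop_above, cs, r_threshold,
                              prob, B, seed if isinstance(seed, int) else None)


@dataclass
class StabilityReport:
    """Aggregated diagnostics for one network estimator."""

    edges: EdgeBootstrap | None = None
    edge_differences: DifferenceTests | None = None
    centrality_differences: dict = field(default_factory=dict)
    cs: dict = field(default_factory=dict)   # index -> CaseDroppingResult

    def cs_coefficients(self) -> dict:
        return {k: v.cs_coefficient for k, v in self.cs.items()}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "cs_coefficients": self.cs_coefficients(),
            "cs_tables": {k: v.to_frame().to_dict(orient="list")
                          for k, v in self.cs.items()},
        }
        if self.edges is not None:
            payload["edges"] = self.edges.to_frame().to_dict(orient="list")
            payload["n_boot"] = self.edges.n_boot
        if self.edge_differences is not None:
            payload["edge_difference_significant"] = \
                self.edge_differences.significant.tolist()
        payload["centrality_difference_significant"] = {
            k: v.significant.tolist()
            for k, v in self.centrality_differences.items()}
        Path(path).write_text(json.dumps(payload, indent=2))
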