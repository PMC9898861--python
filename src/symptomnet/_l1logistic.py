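"""L1-penalized logistic regression solved along a penalty path.

This is the numerical engine behind both network estimators: node-wise
Ising estimation selects a model on this path with the extended BIC, and
the cross-lagged estimator selects with cross-validated deviance.

The objective, in mean-loss form, is

    f(b0, b) = (1/n) * sum_i [ log(1 + exp(eta_i)) - y_i * eta_i ]
               + lam * sum_j |b_j|,       eta = b0 + X b,

with an unpenalized intercept.  Multiplying by n gives the equivalent
"-loglik + lam * n * ||b||_1" form.  The solver is coordinate descent on
an iteratively reweighted least-squares (IRLS) quadratic approximation,
warm-started along a decreasing lambda sequence — the standard approach
for sparse generalized linear models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "CoefficientPath",
    "lambda_max",
    "make_lambda_grid",
    "fit_lasso_path",
    "kkt_violation",
    "logistic_loglik",
]

# glmnet-style clamp on fitted probabilities inside IRLS
_PMIN = 1e-5


@njit(cache=True)
def _cd_one_lambda(X, y, lam, pf, beta0, beta, tol, max_outer, max_inner):
    """Solve one lambda by IRLS + coordinate descent, updating in place.

    Returns the final intercept; `beta` is modified in place.
    """
    n, p = X.shape
    for _ in range(max_outer):
        eta = beta0 + X @ beta
        prob = 1.0 / (1.0 + np.exp(-eta))
        for i in range(n):
            if prob[i] < _PMIN:
                prob[i] = _PMIN
            elif prob[i] > 1.0 - _PMIN:
                prob[i] = 1.0 - _PMIN
        w = prob * (1.0 - prob)
        # working response residual: z - eta = (y - prob)/w
        r = (y - prob) / w
        wxx = np.empty(p)
        for j in range(p):
            s = 0.0
            for i in range(n):
                s += w[i] * X[i, j] * X[i, j]
            wxx[j] = s / n
        wsum = np.sum(w)
        outer_delta = 0.0
        for _ in range(max_inner):
            sweep_delta = 0.0
            # unpenalized intercept
            num = 0.0
            for i in range(n):
                num += w[i] * r[i]
            d0 = num / wsum
            if d0 != 0.0:
                beta0 += d0
                for i in range(n):
                    r[i] -= d0
                if abs(d0) > sweep_delta:
                    sweep_delta = abs(d0)
            for j in range(p):
                if wxx[j] <= 0.0:
                    continue
                g = 0.0
                for i in range(n):
                    g += w[i] * X[i, j] * r[i]
                g = g / n + wxx[j] * beta[j]
                lamj = lam * pf[j]
                # soft threshold
                if g > lamj:
                    bj = (g - lamj) / wxx[j]
                elif g < -lamj:
                    bj = (g + lamj) / wxx[j]
                else:
                    bj = 0.0
                d = bj - beta[j]
                if d != 0.0:
                    beta[j] = bj
                    for i in range(n):
                        r[i] -= d * X[i, j]
                    if abs(d) > sweep_delta:
                        sweep_delta = abs(d)
            if sweep_delta > outer_delta:
                outer_delta = sweep_delta
            if sweep_delta < tol:
                break
        if outer_delta < tol:
            break
    return beta0


@njit(cache=True)
def _path_binary(indptr, indices, n, y, lambdas, pf, tol, max_outer, max_inner):
    """IRLS/CD path specialized to 0/1 predictor columns.

    Column j is represented by the row indices of its ones
    (``indices[indptr[j]:indptr[j+1]]``).  Gradients and residual updates
    touch only those rows; the uniform residual shift from intercept
    updates is carried as a scalar offset, so a full coordinate sweep
    costs O(nnz) instead of O(n * p).  Work buffers are reused across
    the lambda grid.  Mathematically identical to :func:`_cd_one_lambda`
    run per lambda with warm starts.
    """
    p = indptr.shape[0] - 1
    nlam = lambdas.shape[0]
    intercepts = np.empty(nlam)
    coefs = np.zeros((nlam, p))
    loglik = np.empty(nlam)
    ybar = np.mean(y)
    beta0 = np.log(ybar / (1.0 - ybar))
    beta = np.zeros(p)
    eta = np.empty(n)
    w = np.empty(n)
    r = np.empty(n)
    W1 = np.empty(p)
    for k in range(nlam):
        lam = lambdas[k]
        for _ in range(max_outer):
            # linear predictor by scatter over the ones
            for i in range(n):
                eta[i] = beta0
            for j in range(p):
                bj = beta[j]
                if bj != 0.0:
                    for t in range(indptr[j], indptr[j + 1]):
                        eta[indices[t]] += bj
            S_w = 0.0
            S_wr = 0.0
            for i in range(n):
                pr = 1.0 / (1.0 + np.exp(-eta[i]))
                if pr < _PMIN:
                    pr = _PMIN
                elif pr > 1.0 - _PMIN:
                    pr = 1.0 - _PMIN
                wi = pr * (1.0 - pr)
                w[i] = wi
                r[i] = (y[i] - pr) / wi
                S_w += wi
                S_wr += wi * r[i]
            for j in range(p):
                s = 0.0
                for t in range(indptr[j], indptr[j + 1]):
                    s += w[indices[t]]
                W1[j] = s
            c = 0.0  # uniform shift already applied to the working residual
            outer_delta = 0.0
            for _ in range(max_inner):
                sweep_delta = 0.0
                d0 = (S_wr - c * S_w) / S_w
                if d0 != 0.0:
                    beta0 += d0
                    c += d0
                    if abs(d0) > sweep_delta:
                        sweep_delta = abs(d0)
                for j in range(p):
                    if W1[j] <= 0.0:
                        continue
                    wxx = W1[j] / n
                    G = 0.0
                    for t in range(indptr[j], indptr[j + 1]):
                        i = indices[t]
                        G += w[i] * r[i]
                    g = (G - c * W1[j]) / n + wxx * beta[j]
                    lamj = lam * pf[j]
                    if g > lamj:
                        bj = (g - lamj) / wxx
                    elif g < -lamj:
                        bj = (g + lamj) / wxx
                    else:
                        bj = 0.0
                    d = bj - beta[j]
                    if d != 0.0:
                        beta[j] = bj
                        for t in range(indptr[j], indptr[j + 1]):
                            r[indices[t]] -= d
                        S_wr -= d * W1[j]
                        if abs(d) > sweep_delta:
                            sweep_delta = abs(d)
                if sweep_delta > outer_delta:
                    outer_delta = sweep_delta
                if sweep_delta < tol:
                    break
            if outer_delta < tol:
                break
        intercepts[k] = beta0
        coefs[k] = beta
        # stable Bernoulli log-likelihood at the solution
        for i in range(n):
            eta[i] = beta0
        for j in range(p):
            bj = beta[j]
            if bj != 0.0:
                for t in range(indptr[j], indptr[j + 1]):
                    eta[indices[t]] += bj
        ll = 0.0
        for i in range(n):
            e = eta[i]
            if e > 0.0:
                ll += (y[i] - 1.0) * e - np.log1p(np.exp(-e))
            else:
                ll += y[i] * e - np.log1p(np.exp(e))
        loglik[k] = ll
    return intercepts, coefs, loglik


def _to_csc(X):
    """Column-wise indices of the ones of a 0/1 matrix (CSC-like)."""
    n, p = X.shape
    cols = [np.flatnonzero(X[:, j]).astype(np.int64) for j in range(p)]
    indptr = np.zeros(p + 1, dtype=np.int64)
    for j, cj in enumerate(cols):
        indptr[j + 1] = indptr[j] + cj.size
    indices = (np.concatenate(cols) if indptr[-1] > 0
               else np.empty(0, dtype=np.int64))
    return indptr, indices


@njit(cache=True)
def _loglik(X, y, beta0, beta):
    n = X.shape[0]
    eta = beta0 + X @ beta
    ll = 0.0
    for i in range(n):
        e = eta[i]
        if e > 0.0:
            ll += (y[i] - 1.0) * e - np.log1p(np.exp(-e))
        else:
            ll += y[i] * e - np.log1p(np.exp(e))
    return ll


@njit(cache=True)
def _path(X, y, lambdas, pf, tol, max_outer, max_inner):
    n, p = X.shape
    nlam = lambdas.shape[0]
    intercepts = np.empty(nlam)
    coefs = np.zeros((nlam, p))
    loglik = np.empty(nlam)
    ybar = np.mean(y)
    beta0 = np.log(ybar / (1.0 - ybar))
    beta = np.zeros(p)
    for k in range(nlam):
        beta0 = _cd_one_lambda(X, y, lambdas[k], pf, beta0, beta, tol, max_outer, max_inner)
        intercepts[k] = beta0
        coefs[k] = beta
        loglik[k] = _loglik(X, y, beta0, beta)
    return intercepts, coefs, loglik


def logistic_loglik(X, y, intercept, coef):
    """Bernoulli log-likelihood at the given coefficients (numerically stable)."""
    return float(_loglik(np.ascontiguousarray(X, dtype=np.float64),
                         np.ascontiguousarray(y, dtype=np.float64),
                         float(intercept), np.ascontiguousarray(coef, dtype=np.float64)))


@dataclass
class CoefficientPath:
    """Solutions of the L1 logistic problem along a decreasing lambda grid."""

    lambdas: np.ndarray          # shape (nlam,), decreasing
    intercepts: np.ndarray       # shape (nlam,)
    coefs: np.ndarray            # shape (nlam, p), original predictor scale
    loglik: np.ndarray           # shape (nlam,)
    standardized: bool = False
    nonzero: np.ndarray = field(init=False)

    def __post_init__(self):
        self.nonzero = np.count_nonzero(self.coefs, axis=1)


def lambda_max(X, y, standardize: bool = False) -> float:
    """Smallest lambda whose solution has all slopes exactly zero.

    At the intercept-only fit the score of slope j is x_j'(y - ybar)/n;
    the largest absolute score is the threshold below which some slope
    enters the model.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if standardize:
        X = _standardize(X)[0]
    n = X.shape[0]
    score = X.T @ (y - y.mean()) / n
    return float(np.max(np.abs(score)))


def make_lambda_grid(lmax: float, n_lambda: int = 100, min_ratio: float = 1e-3) -> np.ndarray:
    """Log-spaced decreasing grid from lambda_max down to min_ratio * lambda_max."""
    if lmax <= 0:
        # no marginal association at all; a token descending grid
        lmax = 1e-3
    return np.geomspace(lmax, lmax * min_ratio, n_lambda)


def _standardize(X):
    m = X.mean(axis=0)
    s = X.std(axis=0)  # population SD, the glmnet convention
    s_safe = np.where(s > 0, s, 1.0)
    return (X - m) / s_safe, m, s_safe, s > 0


def fit_lasso_path(
    X,
    y,
    lambdas=None,
    *,
    n_lambda: int = 100,
    min_ratio: float = 1e-3,
    standardize: bool = False,
    tol: float = 1e-9,
    max_outer: int = 50,
    max_inner: int = 200,
) -> CoefficientPath:
    """Fit the full L1 logistic path.

    Parameters
    ----------
    X : (n, p) array of predictors (binary or continuous).
    y : (n,) binary outcome; must contain both classes.
    lambdas : optional explicit decreasing grid; default is a 100-point
        log-spaced grid from lambda_max down to ``min_ratio * lambda_max``.
    standardize : fit on z-scored predictors and return coefficients on
        the original scale (the glmnet convention, used by the
        cross-lagged estimator; the Ising estimator fits raw binaries).

    Raises
    ------
    ValueError
        if ``y`` is degenerate (all 0 or all 1); callers dealing with
        low-prevalence symptom nodes must handle that case themselves.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    if X.ndim != 2 or y.shape[0] != X.shape[0]:
        raise ValueError("X must be (n, p) and y of length n")
    ybar = y.mean()
    if ybar <= 0.0 or ybar >= 1.0:
        raise ValueError(
            "outcome is degenerate (all 0 or all 1); L1 logistic path is "
            "undefined — handle this node/outcome upstream"
        )
    is_binary = X.size > 0 and bool(np.all((X == 0.0) | (X == 1.0)))
    p = X.shape[1]
    if standardize and is_binary:
        # Standardizing a 0/1 column is an affine map, so the z-scored
        # lasso problem is equivalent to the raw-binary problem with a
        # per-feature penalty of lam * sd_j; the solution then lands on
        # the original scale directly.  Zero-variance columns can never
        # be selected (infinite penalty).
        s = X.std(axis=0)
        pf = np.where(s > 0, s, np.inf)
        if lambdas is None:
            n = X.shape[0]
            score = np.abs(X.T @ (y - y.mean()) / n)
            with np.errstate(invalid="ignore"):
                lmax = float(np.max(np.where(s > 0, score / pf, 0.0)))
            lambdas = make_lambda_grid(lmax, n_lambda, min_ratio)
        Xf = X
    elif standardize:
        Xf, m, s_safe, _ = _standardize(X)
        pf = np.ones(p)
        if lambdas is None:
            lambdas = make_lambda_grid(lambda_max(Xf, y), n_lambda, min_ratio)
    else:
        Xf = X
        pf = np.ones(p)
        if lambdas is None:
            lambdas = make_lambda_grid(lambda_max(Xf, y), n_lambda, min_ratio)
    lambdas = np.ascontiguousarray(np.asarray(lambdas, dtype=np.float64))
    if np.any(np.diff(lambdas) > 0):
        raise ValueError("lambda grid must be non-increasing")
    if is_binary:
        indptr, indices = _to_csc(Xf)
        intercepts, coefs, loglik = _path_binary(
            indptr, indices, Xf.shape[0], y, lambdas, pf,
            tol, max_outer, max_inner,
        )
    else:
        intercepts, coefs, loglik = _path(
            np.ascontiguousarray(Xf), y, lambdas, pf,
            tol, max_outer, max_inner,
        )
    if standardize and not is_binary:
        coefs = coefs / s_safe
        intercepts = intercepts - coefs @ m
        # log-likelihood is invariant to the affine reparametrization
    # exact floating-point ties at the soft threshold (notably at
    # lambda_max) can leave +-1e-16 residue where the solution is zero
    coefs[np.abs(coefs) < 1e-12] = 0.0
    return CoefficientPath(
        lambdas=lambdas, intercepts=intercepts, coefs=coefs,
        loglik=loglik, standardized=standardize,
    )


def kkt_violation(X, y, lam, intercept, coef) -> float:
    """Maximum KKT (stationarity) violation of a candidate solution.

    Zero at the exact minimizer; used to state and test the convergence
    contract of :func:`fit_lasso_path`.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = X.shape[0]
    eta = intercept + X @ coef
    prob = 1.0 / (1.0 + np.exp(-eta))
    grad = X.T @ (prob - y) / n
    grad0 = np.mean(prob - y)
    viol = abs(grad0)
    for j, b in enumerate(coef):
        if b != 0.0:
            viol = max(viol, abs(grad[j] + lam * np.sign(b)))
        else:
            viol = max(viol, max(0.0, abs(grad[j]) - lam))
    return float(viol)
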