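"""Independent oracles used by the test suite.

These deliberately avoid the package's own fitting code: the logistic MLE is
found by quasi-Newton minimization of the literal negative log-likelihood
from multiple starts, the Firth optimum by brute-force 2-D grid refinement
of the literal penalized likelihood, and the exact Wilcoxon p by full
enumeration of label assignments.
"""

import itertools
import math

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import rankdata


def _negloglik(beta, X, y):
    eta = X @ beta
    return -float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _neggrad(beta, X, y):
    p = expit(X @ beta)
    return -(X.T @ (y - p))


def logistic_mle_oracle(y, x):
    """MLE (intercept, slope) by BFGS on the raw likelihood from multiple starts."""
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones_like(y), np.asarray(x, dtype=float)])
    best = None
    for start in [(0, 0), (0, 2), (0, -2), (2, 0), (-2, 0), (1, 1), (-1, -1)]:
        res = minimize(
            _negloglik, np.array(start, dtype=float), args=(X, y),
            jac=_neggrad, method="BFGS",
            options={"gtol": 1e-12, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best.x


def firth_penalized_loglik(beta, X, y):
    eta = X @ beta
    p = expit(eta)
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    w = p * (1.0 - p)
    info = (X * w[:, None]).T @ X
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -math.inf
    return ll + 0.5 * logdet


def firth_grid_oracle(y, x, half_width=20.0, n_grid=25, refinements=8):
    """Maximize the Firth-penalized likelihood by iterative 2-D grid search."""
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones_like(y), np.asarray(x, dtype=float)])
    center = np.zeros(2)
    hw = half_width
    for _ in range(refinements):
        b0s = np.linspace(center[0] - hw, center[0] + hw, n_grid)
        b1s = np.linspace(center[1] - hw, center[1] + hw, n_grid)
        best_val, best_beta = -math.inf, center
        for b0 in b0s:
            for b1 in b1s:
                val = firth_penalized_loglik(np.array([b0, b1]), X, y)
                if val > best_val:
                    best_val, best_beta = val, np.array([b0, b1])
        center = best_beta
        hw = 2.0 * hw / (n_grid - 1)  # keep the previous grid step inside the new window
    # derivative-free polish: grid zoom alone can stall on a correlated ridge
    res = minimize(
        lambda b: -firth_penalized_loglik(b, X, y), center,
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
    )
    return res.x


def wilcoxon_permutation_oracle(group_a, group_b):
    """Exact two-sided rank-sum p by enumerating all label assignments."""
    a = list(group_a)
    b = list(group_b)
    combined = np.asarray(a + b, dtype=float)
    ranks = rankdata(combined)
    n, n_a = len(combined), len(a)
    observed = float(ranks[:n_a].sum())
    mean = n_a * (n + 1) / 2.0
    dev = abs(observed - mean)
    extreme = total = 0
    for subset in itertools.combinations(range(n), n_a):
        total += 1
        if abs(float(ranks[list(subset)].sum()) - mean) >= dev - 1e-9:
            extreme += 1
    return extreme / total
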