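"""Independent oracles used to cross-check the MILP implementations.

Everything here is deliberately written against the raw mathematical
definitions (plain linear programs, exhaustive enumeration) rather than the
package's own solver assembly, so agreement is meaningful.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.optimize import linprog


def lad_fit(X: np.ndarray, g: np.ndarray) -> float:
    """Least-absolute-deviations objective for a fixed predictor set.

    X is predictors x samples (possibly empty); an intercept is always
    included.  Solved as a plain LP: min sum e, e >= +/- residual.
    """
    D, K = X.shape if X.size else (0, len(g))
    # variables: [beta0, beta_1..D, e_1..K]
    nvar = 1 + D + K
    c = np.zeros(nvar)
    c[1 + D :] = 1.0
    A_ub = np.zeros((2 * K, nvar))
    b_ub = np.zeros(2 * K)
    for k in range(K):
        A_ub[k, 0] = -1.0
        if D:
            A_ub[k, 1 : 1 + D] = -X[:, k]
        A_ub[k, 1 + D + k] = -1.0
        b_ub[k] = -g[k]
        A_ub[K + k, 0] = 1.0
        if D:
            A_ub[K + k, 1 : 1 + D] = X[:, k]
        A_ub[K + k, 1 + D + k] = -1.0
        b_ub[K + k] = g[k]
    bounds = [(None, None)] * (1 + D) + [(0, None)] * K
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
    assert res.status == 0
    return float(res.fun)


def best_subset_objective(
    X: np.ndarray, g: np.ndarray, size: int
) -> tuple[float, tuple[int, ...]]:
    """Exhaustively enumerate all subsets up to ``size``; return (obj, best set)."""
    T = X.shape[0]
    best = (np.inf, ())
    for s in range(size + 1):
        for combo in combinations(range(T), s):
            obj = lad_fit(X[list(combo)], g)
            if obj < best[0] - 1e-12:
                best = (obj, combo)
    return best


def module_score(w_mod: np.ndarray, subset: tuple[int, ...]) -> float:
    """Sum of pair weights inside a node subset."""
    return float(
        sum(w_mod[i, j] for i, j in combinations(sorted(subset), 2))
    )


def best_module(w_mod: np.ndarray, limit: int) -> tuple[float, tuple[int, ...]]:
    """Exhaustive search over all node subsets of size <= limit."""
    n = w_mod.shape[0]
    best = (0.0, ())
    for s in range(min(limit, n) + 1):
        for combo in combinations(range(n), s):
            score = module_score(w_mod, combo)
            if score > best[0] + 1e-12:
                best = (score, combo)
    return best


def bh_by_hand(p: list[float]) -> list[float]:
    """Step-up BH recursion straight from the definition."""
    m = len(p)
    order = np.argsort(p)
    sorted_p = np.asarray(p)[order]
    adj = np.empty(m)
    prev = 1.0
    for i in range(m - 1, -1, -1):
        prev = min(prev, sorted_p[i] * m / (i + 1))
        adj[i] = prev
    out = np.empty(m)
    out[order] = adj
    return out.tolist()
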