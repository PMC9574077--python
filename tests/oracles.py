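"""Independent oracles used to cross-check the implementation.

These deliberately take different computational routes from the package:
the CCR oracle maximizes the ratio form over a fine grid of normalized
multiplier vectors (with an optional derivative-free polish), the relational
oracle runs multistart constrained nonlinear optimization on the fractional
program, Moran's I is evaluated as the naive double sum, and the Jenks
oracle enumerates all contiguous partitions.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.optimize import minimize


def _weight_grid(d: int, g: int) -> np.ndarray:
    """Grid over the d-simplex of normalized weight vectors (d <= 2)."""
    if d == 1:
        return np.ones((1, 1))
    if d == 2:
        t = np.linspace(0.0, 1.0, g)
        return np.column_stack([t, 1.0 - t])
    raise NotImplementedError("oracle grids support at most 2 dimensions")


def ccr_ratio_oracle(X, Y, g: int = 1001, polish: bool = True) -> np.ndarray:
    """Brute-force ratio-form CCR efficiencies of *all* units.

    score_k = max over (v, u) of (u.Y_k / v.X_k) / max_j (u.Y_j / v.X_j).
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    n = X.shape[0]
    V = _weight_grid(X.shape[1], g)
    U = _weight_grid(Y.shape[1], g)
    num = U @ Y.T               # (Gu, n)
    den = V @ X.T               # (Gv, n)
    ratio = num[:, None, :] / den[None, :, :]          # (Gu, Gv, n)
    best = ratio.max(axis=2, keepdims=True)
    eff = ratio / best
    scores = eff.max(axis=(0, 1))
    if not polish:
        return scores

    def negscore(theta, k):
        v = theta[:X.shape[1]] ** 2 + 1e-12
        u = theta[X.shape[1]:] ** 2 + 1e-12
        r = (Y @ u) / (X @ v)
        return -(r[k] / r.max())

    for k in range(n):
        iu, iv = np.unravel_index(eff[:, :, k].argmax(), eff.shape[:2])
        theta0 = np.sqrt(np.concatenate([V[iv] + 1e-9, U[iu] + 1e-9]))
        res = minimize(negscore, theta0, args=(k,), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 2000})
        scores[k] = max(scores[k], -res.fun)
    return scores


def relational_ratio_oracle(X, Z, Y, k: int, n_starts: int = 100,
                            seed: int = 0) -> float:
    """Multistart constrained maximization of the relational ratio form."""
    X, Z, Y = (np.asarray(a, float) for a in (X, Z, Y))
    m, q, s = X.shape[1], Z.shape[1], Y.shape[1]

    def objective(theta):
        v, w, u = theta[:m], theta[m:m + q], theta[m + q:]
        return -(Y[k] @ u) / (X[k] @ v)

    cons = []
    for j in range(X.shape[0]):
        cons.append({"type": "ineq",
                     "fun": (lambda th, j=j: X[j] @ th[:m] - Y[j] @ th[m + q:])})
        cons.append({"type": "ineq",
                     "fun": (lambda th, j=j: X[j] @ th[:m] - Z[j] @ th[m:m + q])})
        cons.append({"type": "ineq",
                     "fun": (lambda th, j=j: Z[j] @ th[m:m + q] - Y[j] @ th[m + q:])})
    scale = np.concatenate([1 / X.max(axis=0), 1 / Z.max(axis=0),
                            1 / Y.max(axis=0)])
    bounds = [(1e-10 * s_, None) for s_ in scale]

    rng = np.random.default_rng(seed)
    best = 0.0
    for _ in range(n_starts):
        theta0 = scale * np.exp(rng.standard_normal(m + q + s))
        res = minimize(objective, theta0, method="SLSQP", bounds=bounds,
                       constraints=cons, options={"maxiter": 300,
                                                  "ftol": 1e-12})
        if res.success:
            theta = res.x
            viol = max((-c["fun"](theta) for c in cons), default=0.0)
            if viol < 1e-8:
                best = max(best, -res.fun)
    return best


def naive_morans_i(x, W) -> float:
    """Direct double-sum evaluation of the Moran statistic."""
    x = np.asarray(x, float)
    W = np.asarray(W, float)
    n = len(x)
    xbar = x.mean()
    s2 = sum((xi - xbar) ** 2 for xi in x) / n
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            num += W[i, j] * (x[i] - xbar) * (x[j] - xbar)
            s0 += W[i, j]
    return num / (s2 * s0)


def exhaustive_jenks(values, k: int) -> float:
    """Minimal within-class SSE over all contiguous partitions."""
    vals = np.sort(np.asarray(list(values), float))
    n = vals.size

    def sse(block):
        return float(np.sum((block - block.mean()) ** 2))

    best = np.inf
    for cuts in combinations(range(1, n), k - 1):
        bounds = [0, *cuts, n]
        total = sum(sse(vals[bounds[i]:bounds[i + 1]]) for i in range(k))
        best = min(best, total)
    return best
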