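"""Independent oracles used by the tests.

Each oracle recomputes a quantity by a route that shares no code with the
implementation it checks: brute-force enumeration for dendrogram/medoid
quantities, and generic scipy optimizers for the convex objectives.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def cophenetic_pairs_bruteforce(merges: np.ndarray, p: int) -> np.ndarray:
    """Cophenetic distance per leaf pair by replaying merges over explicit sets.

    Returns the condensed upper-triangle vector in (i, j), i < j order.
    """
    clusters: dict[int, set[int]] = {i: {i} for i in range(p)}
    coph = np.zeros((p, p))
    for step, (a, b, height, _size) in enumerate(merges):
        left, right = clusters.pop(int(a)), clusters.pop(int(b))
        for i in left:
            for j in right:
                coph[i, j] = coph[j, i] = height
        clusters[p + step] = left | right
    iu = np.triu_indices(p, k=1)
    return coph[iu]


def medoid_bruteforce(members: np.ndarray, dist: np.ndarray) -> int:
    """Exhaustive medoid: the member minimizing summed distance to the rest."""
    best, best_cost = None, np.inf
    for m in members:
        cost = sum(dist[m, o] for o in members if o != m)
        if cost < best_cost - 1e-15:
            best, best_cost = int(m), cost
    return best


def group_sparse_oracle(X: np.ndarray, Y: np.ndarray, assignment: np.ndarray,
                        gamma1: float, gamma2: float, eps: float = 1e-9,
                        maxiter: int = 20000) -> np.ndarray:
    """Minimize ||W^T X - Y||_F^2 + g1*sum_k h(||W_k||) + g2*sum_i h(||w^i||)
    with a generic quasi-Newton optimizer; h is the eps-Huberized absolute value.

    X is d x n, Y is c x n; returns the d x c minimizer.
    """
    d, n = X.shape
    c = Y.shape[0]
    K = int(assignment.max()) + 1

    def huber(t):
        return np.where(t >= eps, t, (t**2 + eps**2) / (2 * eps))

    def dhuber_over_t(t):
        # h'(t)/t, safe at t=0
        return np.where(t >= eps, 1.0 / np.maximum(t, eps), 1.0 / eps)

    def fun_grad(w):
        W = w.reshape(d, c)
        R = X.T @ W - Y.T  # n x c
        row = np.linalg.norm(W, axis=1)
        grp = np.sqrt(np.bincount(assignment, weights=row**2, minlength=K))
        f = float(np.sum(R**2) + gamma1 * huber(grp).sum() + gamma2 * huber(row).sum())
        G = 2.0 * X @ R
        G += gamma1 * (dhuber_over_t(grp)[assignment])[:, None] * W
        G += gamma2 * dhuber_over_t(row)[:, None] * W
        return f, G.ravel()

    res = optimize.minimize(fun_grad, np.zeros(d * c), jac=True, method="L-BFGS-B",
                            options={"maxiter": maxiter, "ftol": 1e-16, "gtol": 1e-12})
    return res.x.reshape(d, c)


def ridge_oracle(X: np.ndarray, Y: np.ndarray, gamma: float,
                 maxiter: int = 20000) -> np.ndarray:
    """Generic-optimizer minimizer of sum_i ||W^T x_i - y_i||^2 + gamma ||W||_F^2."""
    d, _ = X.shape
    c = Y.shape[0]

    def fun_grad(w):
        W = w.reshape(d, c)
        R = X.T @ W - Y.T
        f = float(np.sum(R**2) + gamma * np.sum(W**2))
        G = 2.0 * X @ R + 2.0 * gamma * W
        return f, G.ravel()

    res = optimize.minimize(fun_grad, np.zeros(d * c), jac=True, method="L-BFGS-B",
                            options={"maxiter": maxiter, "ftol": 1e-18, "gtol": 1e-14})
    return res.x.reshape(d, c)


def svr_dual_objective(beta: np.ndarray, K: np.ndarray, y: np.ndarray,
                       eps_tube: float) -> float:
    """Dual objective -1/2 b^T K b - eps*||b||_1 + y^T b (to be maximized)."""
    return float(-0.5 * beta @ K @ beta - eps_tube * np.abs(beta).sum() + y @ beta)


def svr_dual_oracle(K: np.ndarray, y: np.ndarray, C: float, eps_tube: float) -> float:
    """Maximize the SVR dual over beta in [-C, C]^n with sum(beta) = 0 (SLSQP)."""
    n = len(y)

    def neg(beta):
        return -svr_dual_objective(beta, K, y, eps_tube)

    def neg_grad(beta):
        return -(-K @ beta - eps_tube * np.sign(beta) + y)

    cons = {"type": "eq", "fun": lambda b: b.sum(), "jac": lambda b: np.ones(n)}
    best = -np.inf
    for start_scale in (0.0, 0.1):
        x0 = start_scale * np.clip(y - y.mean(), -C, C)
        res = optimize.minimize(neg, x0, jac=neg_grad, method="SLSQP",
                                bounds=[(-C, C)] * n, constraints=[cons],
                                options={"maxiter": 2000, "ftol": 1e-14})
        best = max(best, -res.fun)
    return best


def ols_weights(X_samples: np.ndarray, Y_samples: np.ndarray) -> np.ndarray:
    W, *_ = np.linalg.lstsq(X_samples, Y_samples, rcond=None)
    return W
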