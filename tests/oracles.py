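"""Independent brute-force oracles used to validate the fast implementations.

Every function here deliberately uses a different algorithm (and where
possible a different library) than the code under test.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import optimize, stats
from scipy.sparse.csgraph import dijkstra
from scipy.special import ndtr


def tau_b_bruteforce(x, y) -> float:
    """Kendall tau-b by explicit O(n^2) concordant/discordant pair counting."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    concordant = discordant = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) / 2
    nx_ = sum(
        c * (c - 1) / 2 for c in np.unique(x, return_counts=True)[1]
    )
    ny_ = sum(
        c * (c - 1) / 2 for c in np.unique(y, return_counts=True)[1]
    )
    denom = np.sqrt((n0 - nx_) * (n0 - ny_))
    return (concordant - discordant) / denom if denom > 0 else 0.0


def signed_rank_exact_p(baseline, endpoint) -> float:
    """Two-sided exact signed-rank p by full enumeration of 2^n sign patterns."""
    d = np.asarray(baseline, float) - np.asarray(endpoint, float)
    d = d[d != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    total = ranks.sum()
    mu = total / 2.0
    v_obs = ranks[d > 0].sum()
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        v = float(np.dot(signs, ranks))
        if abs(v - mu) >= abs(v_obs - mu) - 1e-9:
            count += 1
    return count / 2.0**n


def glasso_objective(K, S, lam) -> float:
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        return np.inf
    l1_off = np.abs(K).sum() - np.abs(np.diag(K)).sum()
    return float(-logdet + np.sum(S * K) + lam * l1_off)


def glasso_oracle_3x3(S, lam, n_starts: int = 40, seed: int = 0) -> float:
    """Minimum penalized objective over 3x3 symmetric PD matrices.

    Coarse random multistart around inv(S) followed by Nelder-Mead
    refinement on the 6 free entries.  Returns the best objective found.
    """

    def unpack(theta):
        K = np.empty((3, 3))
        K[0, 0], K[1, 1], K[2, 2] = theta[:3]
        K[0, 1] = K[1, 0] = theta[3]
        K[0, 2] = K[2, 0] = theta[4]
        K[1, 2] = K[2, 1] = theta[5]
        return K

    def f(theta):
        val = glasso_objective(unpack(theta), S, lam)
        return val if np.isfinite(val) else 1e12  # non-PD barrier

    K0 = np.linalg.inv(S)
    base = np.array([K0[0, 0], K0[1, 1], K0[2, 2], K0[0, 1], K0[0, 2], K0[1, 2]])
    rng = np.random.default_rng(seed)
    best = np.inf
    starts = [base] + [
        base + rng.normal(scale=0.3, size=6) for _ in range(n_starts)
    ]
    for s0 in starts:
        res = optimize.minimize(
            f, s0, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 6000,
                     "maxfev": 8000},
        )
        best = min(best, res.fun)
    return best


def partial_corr_3x3_recursion(R) -> np.ndarray:
    """Partial correlations of 3 variables via the first-order recursion."""
    out = np.zeros((3, 3))
    for i, j, k in [(0, 1, 2), (0, 2, 1), (1, 2, 0)]:
        num = R[i, j] - R[i, k] * R[j, k]
        den = np.sqrt((1 - R[i, k] ** 2) * (1 - R[j, k] ** 2))
        out[i, j] = out[j, i] = num / den
    return out


def _distance_matrix(weights):
    p = weights.shape[0]
    D = np.full((p, p), np.inf)
    for i in range(p):
        for j in range(p):
            if i != j and abs(weights[i, j]) > 1e-10:
                D[i, j] = 1.0 / abs(weights[i, j])
    return dijkstra(np.where(np.isinf(D), 0, D), directed=False,
                    unweighted=False, indices=None), D


def closeness_oracle(weights) -> np.ndarray:
    """Closeness = 1 / mean shortest-path distance to reachable nodes."""
    p = weights.shape[0]
    sp, _ = _distance_matrix(weights)
    out = np.zeros(p)
    for v in range(p):
        d = np.array([sp[v, u] for u in range(p) if u != v])
        d = d[np.isfinite(d)]
        if d.size:
            out[v] = 1.0 / d.mean()
    return out


def betweenness_oracle(weights, tol: float = 1e-9) -> np.ndarray:
    """Unnormalized betweenness by enumerating all shortest paths.

    Shortest-path distances come from scipy's Dijkstra; the paths
    themselves are enumerated by depth-first search over distance-tight
    edges, independently of any Brandes-style accumulation.
    """
    p = weights.shape[0]
    sp, D = _distance_matrix(weights)
    between = np.zeros(p)
    for s in range(p):
        for t in range(p):
            if t <= s or not np.isfinite(sp[s, t]):
                continue
            paths: list[list[int]] = []

            def extend(node, acc):
                if node == t:
                    paths.append(acc[:])
                    return
                for nxt in range(p):
                    if np.isfinite(D[node, nxt]) and abs(
                        sp[s, node] + D[node, nxt] + sp[nxt, t] - sp[s, t]
                    ) < tol and nxt not in acc:
                        acc.append(nxt)
                        extend(nxt, acc)
                        acc.pop()

            extend(s, [s])
            if not paths:
                continue
            for path in paths:
                for v in path[1:-1]:
                    between[v] += 1.0 / len(paths)
    return between


def ordinal_mean_quadrature(cutpoints, n_grid: int = 200001) -> float:
    """Implied ordinal mean under a standard normal latent, by quadrature.

    Integrates category * pdf over a fine grid, independent of the
    Phi-difference shortcut used by the generator.
    """
    z = np.linspace(-10, 10, n_grid)
    pdf = np.exp(-0.5 * z**2) / np.sqrt(2 * np.pi)
    cat = np.searchsorted(np.asarray(cutpoints, float), z)
    return float(np.trapezoid(cat * pdf, z))


def category_probs_phi(cutpoints) -> np.ndarray:
    """Closed-form category probabilities Phi(c_k) - Phi(c_{k-1})."""
    c = np.concatenate([[-np.inf], np.asarray(cutpoints, float), [np.inf]])
    return np.diff(ndtr(c))


def residuals_normal_equations(scores, delays) -> np.ndarray:
    """OLS residuals via the explicit (X'X)^-1 X'y normal equations."""
    X = np.column_stack([np.ones(len(delays)), delays])
    XtX_inv = np.linalg.inv(X.T @ X)
    out = np.empty_like(np.asarray(scores, float))
    for j in range(scores.shape[1]):
        beta = XtX_inv @ (X.T @ scores[:, j])
        out[:, j] = scores[:, j] - X @ beta
    return out
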