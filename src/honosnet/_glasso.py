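"""Numba kernels for the graphical-lasso coordinate descent.

The permutation comparison test and the case-drop bootstrap re-estimate the
whole regularization path thousands of times on 12-variable problems, so the
inner solver is compiled.  The algorithm is the classic block coordinate
descent on the working covariance W: each column's sub-problem is an
L1-penalized regression solved by cyclic coordinate descent, and the
precision matrix is reconstructed from the final (W, B) pair.  Only
off-diagonal entries are penalized, so the working covariance keeps the
sample diagonal.

Convergence is certified by a true primal-dual gap: the off-diagonal of
``W - S`` is clipped into the dual-feasible box ``[-lam, lam]`` and the
primal objective ``-logdet K + tr(S K) + lam * |K|_1,off`` is compared with
the dual value ``logdet(W_feasible) + p``.  The gap is nonnegative and zero
exactly at the optimum, so it cannot trigger a spurious early exit the way
the usual reconstruction-based pseudo-gap can.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _chol_logdet(A):
    """Cholesky log-determinant; returns (ok, logdet)."""
    p = A.shape[0]
    L = np.zeros((p, p))
    logdet = 0.0
    for i in range(p):
        for j in range(i + 1):
            acc = A[i, j]
            for k in range(j):
                acc -= L[i, k] * L[j, k]
            if i == j:
                if acc <= 0.0:
                    return False, 0.0
                L[i, i] = np.sqrt(acc)
                logdet += np.log(L[i, i])
            else:
                L[i, j] = acc / L[j, j]
    return True, 2.0 * logdet


@njit(cache=True)
def _precision_from_wb(W, B):
    p = W.shape[0]
    K = np.zeros((p, p))
    for j in range(p):
        dot = 0.0
        for l in range(p):
            if l != j:
                dot += W[l, j] * B[l, j]
        kjj = 1.0 / (W[j, j] - dot)
        K[j, j] = kjj
        for k in range(p):
            if k != j:
                K[k, j] = -B[k, j] * kjj
    # symmetrize (columns are solved one at a time)
    for i in range(p):
        for j in range(i + 1, p):
            v = 0.5 * (K[i, j] + K[j, i])
            K[i, j] = v
            K[j, i] = v
    return K


@njit(cache=True)
def _duality_gap(S, W, K, lam):
    p = S.shape[0]
    ok_k, logdet_k = _chol_logdet(K)
    if not ok_k:
        return np.inf
    tr_sk = 0.0
    l1_off = 0.0
    for i in range(p):
        for j in range(p):
            tr_sk += S[i, j] * K[i, j]
            if i != j:
                l1_off += abs(K[i, j])
    primal = -logdet_k + tr_sk + lam * l1_off
    # project W onto the dual-feasible box around S
    Wf = np.empty((p, p))
    for i in range(p):
        for j in range(p):
            if i == j:
                Wf[i, j] = S[i, j]
            else:
                u = W[i, j] - S[i, j]
                if u > lam:
                    u = lam
                elif u < -lam:
                    u = -lam
                Wf[i, j] = S[i, j] + u
    ok_w, logdet_w = _chol_logdet(Wf)
    if not ok_w:
        return np.inf
    return primal - (logdet_w + p)


@njit(cache=True)
def glasso_cd(S, lam, W, B, max_sweeps, tol, inner_tol, inner_max):
    """Graphical lasso via block coordinate descent.

    ``W`` (working covariance) and ``B`` (per-column lasso coefficients) are
    modified in place, enabling warm starts along a lambda path.  Returns
    ``(K, gap, sweeps)`` where ``gap`` is the duality gap at exit; the
    caller decides whether a non-converged gap is an error.
    """
    p = S.shape[0]
    K = np.zeros((p, p))
    gap = np.inf
    sweeps = 0
    for sweep in range(max_sweeps):
        sweeps = sweep + 1
        for j in range(p):
            # cyclic coordinate descent on column j's penalized regression:
            # full passes establish the active set, which is then iterated
            # to convergence before the next full-pass check
            for _ in range(inner_max):
                max_delta = 0.0
                for k in range(p):
                    if k == j:
                        continue
                    r = S[k, j]
                    for l in range(p):
                        if l != j and l != k:
                            r -= W[k, l] * B[l, j]
                    old = B[k, j]
                    if r > lam:
                        new = (r - lam) / W[k, k]
                    elif r < -lam:
                        new = (r + lam) / W[k, k]
                    else:
                        new = 0.0
                    if new != old:
                        B[k, j] = new
                        delta = abs(new - old)
                        if delta > max_delta:
                            max_delta = delta
                if max_delta < inner_tol:
                    break
                for _ in range(inner_max):
                    max_delta_a = 0.0
                    for k in range(p):
                        if k == j or B[k, j] == 0.0:
                            continue
                        r = S[k, j]
                        for l in range(p):
                            if l != j and l != k:
                                r -= W[k, l] * B[l, j]
                        old = B[k, j]
                        if r > lam:
                            new = (r - lam) / W[k, k]
                        elif r < -lam:
                            new = (r + lam) / W[k, k]
                        else:
                            new = 0.0
                        if new != old:
                            B[k, j] = new
                            delta = abs(new - old)
                            if delta > max_delta_a:
                                max_delta_a = delta
                    if max_delta_a < inner_tol:
                        break
            for k in range(p):
                if k == j:
                    continue
                acc = 0.0
                for l in range(p):
                    if l != j:
                        acc += W[k, l] * B[l, j]
                W[k, j] = acc
                W[j, k] = acc
        K = _precision_from_wb(W, B)
        gap = _duality_gap(S, W, K, lam)
        if gap < tol:
            break
    return K, gap, sweeps


@njit(cache=True)
def glasso_path(S, lams, n, gamma, max_sweeps, tol, inner_tol, inner_max):
    """Warm-started lambda path with per-point EBIC.

    Returns stacked precisions, duality gaps, EBIC values and edge counts.
    The edge tolerance (1e-10) matches the package-wide EDGE_TOL.
    """
    p = S.shape[0]
    m = lams.size
    Ks = np.zeros((m, p, p))
    gaps = np.empty(m)
    ebics = np.empty(m)
    edges = np.zeros(m, dtype=np.int64)
    W = S.copy()
    B = np.zeros((p, p))
    logp = np.log(p)
    logn = np.log(n)
    for t in range(m):
        K, gap, _ = glasso_cd(S, lams[t], W, B, max_sweeps, tol,
                              inner_tol, inner_max)
        Ks[t] = K
        gaps[t] = gap
        ok, logdet = _chol_logdet(K)
        if not ok:
            gaps[t] = np.inf
            ebics[t] = np.inf
            continue
        tr_sk = 0.0
        for i in range(p):
            for j in range(p):
                tr_sk += S[i, j] * K[i, j]
        E = 0
        for i in range(p):
            for j in range(i + 1, p):
                if abs(K[i, j]) > 1e-10:
                    E += 1
        L = (n / 2.0) * (logdet - tr_sk)
        ebics[t] = -2.0 * L + E * logn + 4.0 * E * gamma * logp
        edges[t] = E
    return Ks, gaps, ebics, edges


@njit(cache=True)
def tau_b_matrix_kernel(X):
    """All-pairs Kendall tau-b by direct pair counting, O(p^2 n^2 / 4).

    Constant columns keep tau 0 off the diagonal (the caller warns).
    """
    n, p = X.shape
    tau = np.eye(p)
    n0 = n * (n - 1) / 2.0
    n_ties = np.zeros(p)
    for j in range(p):
        xs = np.sort(X[:, j].copy())
        run = 1
        t = 0.0
        for i in range(1, n):
            if xs[i] == xs[i - 1]:
                run += 1
            else:
                t += run * (run - 1) / 2.0
                run = 1
        t += run * (run - 1) / 2.0
        n_ties[j] = t
    for a in range(p):
        for b in range(a):
            num = 0.0
            for i in range(n):
                xa = X[i, a]
                xb = X[i, b]
                for k in range(i):
                    prod = (xa - X[k, a]) * (xb - X[k, b])
                    if prod > 0.0:
                        num += 1.0
                    elif prod < 0.0:
                        num -= 1.0
            da = n0 - n_ties[a]
            db = n0 - n_ties[b]
            if da > 0.0 and db > 0.0:
                val = num / np.sqrt(da * db)
                tau[a, b] = val
                tau[b, a] = val
    return tau
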