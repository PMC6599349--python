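"""Sparse partial-correlation network estimation.

The estimation chain is the standard regularized Gaussian-graphical-model
pipeline for ordinal psychometric data:

1. **SKEPTIC correlation** — the latent correlation matrix is estimated
   entrywise as ``sin(pi/2 * tau_b)`` from Kendall rank correlations, which
   is consistent under a Gaussian copula regardless of the (ordinal)
   margins.  Indefinite estimates are repaired by eigenvalue clipping.
2. **Graphical lasso path** — L1-penalized precision matrices along a
   log-spaced lambda path from ``lambda_max`` (the largest absolute
   off-diagonal correlation, where the graph is empty) down to
   ``lambda_max * lambda_min_ratio``.
3. **EBIC model selection** — the extended Bayesian information criterion
   ``-2 L + E log n + 4 E gamma log p`` picks the path point; ``gamma = 0``
   reduces to the ordinary BIC.  Ties break toward the sparser (larger
   lambda) model.
4. The selected precision matrix is converted to partial correlations
   ``w_ij = -K_ij / sqrt(K_ii K_jj)``, the network's edge weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._glasso import glasso_cd, glasso_path, tau_b_matrix_kernel
from .items import ITEM_LABELS

#: Entries of the precision matrix below this magnitude count as zero edges.
EDGE_TOL = 1e-10

#: Eigenvalue floor used when repairing an indefinite correlation estimate.
PSD_CLIP = 1e-4


class GlassoConvergenceError(RuntimeError):
    """The coordinate descent did not reach the duality-gap tolerance."""


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric unit-diagonal correlation estimate (possibly PSD-repaired)."""

    values: np.ndarray
    psd_repaired: bool = False

    @property
    def p(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class WeightedNetwork:
    """Partial-correlation network: symmetric weights, zero diagonal."""

    weights: np.ndarray
    labels: tuple[str, ...] = ITEM_LABELS

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("weights must be symmetric")
        if np.any(np.abs(np.diag(w)) > 1e-12):
            raise ValueError("weights must have a zero diagonal")
        object.__setattr__(self, "weights", w)
        if len(self.labels) != w.shape[0]:
            object.__setattr__(
                self, "labels", tuple(f"V{i + 1}" for i in range(w.shape[0]))
            )

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    @property
    def edge_count(self) -> int:
        iu = np.triu_indices(self.p, k=1)
        return int(np.sum(np.abs(self.weights[iu]) > EDGE_TOL))

    def edge_mask(self) -> np.ndarray:
        iu = np.triu_indices(self.p, k=1)
        return np.abs(self.weights[iu]) > EDGE_TOL


@dataclass(frozen=True)
class GlassoFit:
    """Record of a whole lambda path and the EBIC selection over it."""

    lambda_path: np.ndarray
    precisions: tuple[np.ndarray, ...]
    ebic_values: np.ndarray
    gamma: float
    selected_index: int
    n: int
    edge_counts: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def selected_lambda(self) -> float:
        return float(self.lambda_path[self.selected_index])

    @property
    def selected_precision(self) -> np.ndarray:
        return self.precisions[self.selected_index]


def kendall_tau_b(x: np.ndarray, y: np.ndarray) -> float:
    """Kendall's tau-b between two vectors (tie-corrected).

    A constant vector has no rank ordering; the correlation is undefined and
    0 is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length vectors with n >= 2")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        warnings.warn("constant vector: tau undefined, returning 0", stacklevel=2)
        return 0.0
    tau = stats.kendalltau(x, y).statistic
    return float(tau)


def _tau_b_matrix(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs tau-b matrix; returns (tau, constant_column_mask).

    Moderate n uses a compiled direct pair-count kernel; large n falls back
    to per-pair O(n log n) calls.
    """
    n, p = X.shape
    constant = np.ptp(X, axis=0) == 0.0
    if n <= 2000:
        tau = tau_b_matrix_kernel(np.ascontiguousarray(X, dtype=float))
    else:
        tau = np.eye(p)
        for i in range(p):
            for j in range(i):
                if constant[i] or constant[j]:
                    t = 0.0
                else:
                    t = stats.kendalltau(X[:, i], X[:, j]).statistic
                tau[i, j] = tau[j, i] = t
    return tau, constant


def skeptic_correlation(residuals: np.ndarray) -> CorrelationMatrix:
    """Nonparanormal SKEPTIC estimate of the latent correlation matrix.

    Applies ``sin(pi/2 * tau_b)`` entrywise.  If the resulting matrix is not
    positive semi-definite its eigenvalues are clipped at 1e-4 and the
    matrix rescaled back to unit diagonal (``psd_repaired`` is then set).
    Constant columns get zero correlations with a warning.
    """
    X = np.asarray(residuals, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("residuals must be an (n >= 3, p) matrix")
    tau, constant = _tau_b_matrix(X)
    if np.any(constant):
        warnings.warn(
            f"constant column(s) at indices {np.flatnonzero(constant).tolist()}:"
            " correlations set to 0",
            stacklevel=2,
        )
    R = np.sin(np.pi / 2.0 * tau)
    np.fill_diagonal(R, 1.0)
    R = 0.5 * (R + R.T)

    repaired = False
    min_eig = np.min(np.linalg.eigvalsh(R))
    if min_eig < 1e-8:
        vals, vecs = np.linalg.eigh(R)
        vals = np.clip(vals, PSD_CLIP, None)
        R = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        R = 0.5 * (R + R.T)
        np.fill_diagonal(R, 1.0)
        repaired = True
    return CorrelationMatrix(values=R, psd_repaired=repaired)


def graphical_lasso(
    S: CorrelationMatrix | np.ndarray,
    lam: float,
    max_sweeps: int = 500,
    tol: float = 1e-6,
    _warm: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """L1-penalized precision estimate for one penalty value.

    Maximizes ``log det K - tr(S K) - lam * sum_{i != j} |K_ij|`` by block
    coordinate descent, converged when the duality gap is below ``tol``.
    ``lam = 0`` returns the plain inverse.  Raises
    :class:`GlassoConvergenceError` if the gap tolerance is not reached.
    """
    S = S.values if isinstance(S, CorrelationMatrix) else np.asarray(S, float)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if lam == 0.0:
        return np.linalg.inv(S)
    if _warm is None:
        W = S.copy()
        B = np.zeros_like(S)
    else:
        W, B = _warm
    K, gap, _ = glasso_cd(S, float(lam), W, B, max_sweeps, tol, 1e-10, 200)
    if abs(gap) >= tol:
        raise GlassoConvergenceError(
            f"graphical lasso did not converge: duality gap {gap:.3e} "
            f"after {max_sweeps} sweeps (lambda={lam:.4g})"
        )
    return K


def ebic(
    K: np.ndarray,
    S: CorrelationMatrix | np.ndarray,
    n: int,
    gamma: float = 0.0,
) -> float:
    """Extended BIC of a precision matrix against a correlation estimate.

    ``EBIC = -2 L + E log n + 4 E gamma log p`` with Gaussian log-likelihood
    ``L = (n/2)(log det K - tr(S K))`` and E the number of nonzero
    off-diagonal upper-triangle entries.
    """
    S = S.values if isinstance(S, CorrelationMatrix) else np.asarray(S, float)
    if n < 3:
        raise ValueError("n must be >= 3")
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    p = K.shape[0]
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0 or not np.isfinite(logdet):
        raise ValueError("precision matrix must be positive definite")
    L = (n / 2.0) * (logdet - float(np.sum(S * K)))
    iu = np.triu_indices(p, k=1)
    E = int(np.sum(np.abs(K[iu]) > EDGE_TOL))
    return float(-2.0 * L + E * np.log(n) + 4.0 * E * gamma * np.log(p))


def precision_to_partial(
    K: np.ndarray, labels: tuple[str, ...] | None = None
) -> WeightedNetwork:
    """Convert a precision matrix to the partial-correlation network.

    ``w_ij = -K_ij / sqrt(K_ii K_jj)`` off the diagonal, zero on it.
    """
    K = np.asarray(K, dtype=float)
    d = np.diag(K)
    if np.any(d <= 0):
        raise ValueError("precision diagonal must be positive")
    w = -K / np.sqrt(np.outer(d, d))
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    # exact zeros in K must stay exact zeros in the network
    w[np.abs(K) <= EDGE_TOL] = 0.0
    labels = labels if labels is not None else (
        ITEM_LABELS if K.shape[0] == len(ITEM_LABELS) else None
    )
    if labels is None:
        return WeightedNetwork(weights=w, labels=())
    return WeightedNetwork(weights=w, labels=tuple(labels))


def estimate_network(
    residuals: np.ndarray,
    gamma: float = 0.0,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    labels: tuple[str, ...] | None = None,
) -> tuple[WeightedNetwork, GlassoFit]:
    """Full EBIC-glasso estimation from a residual (or score) matrix.

    The pipeline preset for this analysis uses ``gamma = 0`` (ordinary
    BIC); the library-wide default elsewhere is 0.5.  Deterministic: the
    same input always yields the same network.
    """
    X = np.asarray(residuals, dtype=float)
    n = X.shape[0]
    S = skeptic_correlation(X)
    offdiag = np.abs(S.values - np.diag(np.diag(S.values)))
    lam_max = float(offdiag.max())
    if lam_max <= 0.0:
        # all correlations zero: the empty network, a single degenerate point
        K = np.diag(1.0 / np.diag(S.values))
        fit = GlassoFit(
            lambda_path=np.array([0.0]),
            precisions=(K,),
            ebic_values=np.array([ebic(K, S, n, gamma)]),
            gamma=gamma,
            selected_index=0,
            n=n,
            edge_counts=np.array([0]),
        )
        return precision_to_partial(K, labels), fit

    path = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)
    Ks, gaps, ebics, edge_counts = glasso_path(
        S.values, path, n, float(gamma), 500, 1e-6, 1e-10, 200
    )
    if np.any(gaps >= 1e-6):
        worst = int(np.argmax(gaps))
        raise GlassoConvergenceError(
            f"graphical lasso did not converge at lambda={path[worst]:.4g} "
            f"(duality gap {gaps[worst]:.3e})"
        )
    drops = np.flatnonzero(np.diff(edge_counts) < -2)
    if drops.size:
        # glasso paths are not guaranteed monotone; large dips are logged
        warnings.warn(
            f"edge count dropped from {edge_counts[drops[0]]} to "
            f"{edge_counts[drops[0] + 1]} while lambda decreased",
            stacklevel=2,
        )
    precisions = [Ks[i] for i in range(n_lambda)]
    selected = int(np.argmin(ebics))  # first minimum = sparser on ties
    net = precision_to_partial(precisions[selected], labels)
    fit = GlassoFit(
        lambda_path=path,
        precisions=tuple(precisions),
        ebic_values=ebics,
        gamma=gamma,
        selected_index=selected,
        n=n,
        edge_counts=edge_counts,
    )
    return net, fit
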