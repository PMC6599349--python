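"""The individual-scores analysis arm.

Per-item paired Wilcoxon signed-rank tests of baseline vs end-point scores,
the treatment-response classification (reaching the non-severe level at end
point) and its cohort proportion, and a logistic regression of response on
the 12 baseline items, age and gender.

The signed-rank statistic V is the sum of the ranks of positive differences
(baseline minus end point), so improvement produces large V.  Zero
differences are dropped and midranks handle ties.  For 25 or fewer nonzero
differences the two-sided p-value is exact, computed from the full sign-flip
null distribution of V (a subset-sum convolution over the doubled midranks);
beyond that a normal approximation with tie and continuity correction is
used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats
from scipy.special import expit, ndtr

from .data import (
    NON_SEVERE,
    CohortTable,
    ItemProfile,
    classify_severity,
)
from .items import ITEM_LABELS, N_ITEMS

RESPONDER = "responder"
NON_RESPONDER = "non-responder"

#: Largest number of nonzero differences for which the exact p is computed.
EXACT_THRESHOLD = 25

#: |log-odds| beyond which a coefficient signals (quasi-)separation.
SEPARATION_BOUND = 15.0


@dataclass(frozen=True)
class WilcoxonResult:
    item: str
    V: float
    p_value: float
    n_effective: int
    degenerate: bool = False
    method: str = "exact"


@dataclass(frozen=True)
class LogisticFit:
    predictors: tuple[str, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    wald_p_values: np.ndarray
    converged: bool
    separation_flag: bool
    n_used: int
    n_dropped: int
    deviance: float


def _exact_signed_rank_p(ranks2: np.ndarray, v2: float) -> float:
    """Exact two-sided p for the signed-rank test by convolution.

    ``ranks2`` are the midranks doubled (hence integers); ``v2`` the doubled
    observed statistic.  Enumerates the distribution of V over all 2^n
    equiprobable sign assignments via a subset-sum table, then sums the
    probability of outcomes at least as far from the null mean as observed.
    The distribution is symmetric about total/2, so this matches the usual
    doubled one-tail convention.
    """
    ranks2 = ranks2.astype(np.int64)
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    support = np.arange(total + 1)
    mu = total / 2.0
    extreme = np.abs(support - mu) >= abs(v2 - mu) - 1e-9
    return float(min(1.0, counts[extreme].sum()))


def paired_wilcoxon(
    baseline_scores: np.ndarray,
    endpoint_scores: np.ndarray,
    item: str = "",
    exact_threshold: int = EXACT_THRESHOLD,
) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test of baseline vs end-point scores."""
    x = np.asarray(baseline_scores, dtype=float)
    y = np.asarray(endpoint_scores, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("baseline and endpoint must be equal-length vectors")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    d = d[d != 0.0]
    n_eff = d.size
    if n_eff == 0:
        return WilcoxonResult(item, 0.0, 1.0, 0, degenerate=True, method="degenerate")

    ranks = stats.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())

    if n_eff <= exact_threshold:
        p = _exact_signed_rank_p(np.round(ranks * 2), v * 2)
        method = "exact"
    else:
        mu = n_eff * (n_eff + 1) / 4.0
        # tie correction over groups of equal |d|
        _, tie_counts = np.unique(np.abs(d), return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        var = n_eff * (n_eff + 1) * (2 * n_eff + 1) / 24.0 - tie_term / 48.0
        if var <= 0:
            return WilcoxonResult(item, v, 1.0, n_eff, degenerate=True,
                                  method="degenerate")
        diff = v - mu
        cc = 0.5 * np.sign(diff) if diff != 0 else 0.0
        z = (diff - cc) / np.sqrt(var)
        p = float(min(1.0, 2.0 * (1.0 - ndtr(abs(z)))))
        method = "approx"
    return WilcoxonResult(item, v, p, n_eff, degenerate=False, method=method)


def cohort_wilcoxon(cohort: CohortTable) -> list[WilcoxonResult]:
    """Per-item signed-rank tests across the whole cohort."""
    base = cohort.baseline_matrix()
    end = cohort.endpoint_matrix()
    return [
        paired_wilcoxon(base[:, j], end[:, j], item=ITEM_LABELS[j])
        for j in range(N_ITEMS)
    ]


def response_status(endpoint: ItemProfile) -> str:
    """Responder iff the end-point profile is non-severe."""
    return RESPONDER if classify_severity(endpoint) == NON_SEVERE else NON_RESPONDER


def response_proportion(cohort: CohortTable) -> tuple[int, float]:
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    count = sum(
        1 for r in cohort.records if response_status(r.endpoint) == RESPONDER
    )
    return count, count / len(cohort)


def _check_design_rank(X: np.ndarray, names: list[str]) -> None:
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    if X.shape[1] > len(diag):
        bad += [names[p] for p in piv[len(diag):]]
    if bad:
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def _deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def _irls_logistic(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 100,
    score_tol: float = 1e-8,
    dev_tol: float = 1e-10,
    deviance_trace: list[float] | None = None,
) -> tuple[np.ndarray, np.ndarray, bool, float]:
    """Logistic ML fit by iteratively reweighted least squares.

    Newton steps with step-halving so the deviance never increases.
    Convergence when the score's max absolute entry drops below
    ``score_tol`` or the relative deviance change below ``dev_tol``.
    Returns (coefficients, covariance, converged, deviance).
    """
    n, p = X.shape
    beta = np.zeros(p)
    mu = expit(X @ beta)
    dev = _deviance(y, mu)
    if deviance_trace is not None:
        deviance_trace.append(dev)
    converged = False
    info = np.eye(p)
    for _ in range(max_iter):
        w = np.clip(mu * (1 - mu), 1e-10, None)
        score = X.T @ (y - mu)
        info = X.T @ (X * w[:, None])
        if np.max(np.abs(score)) < score_tol:
            converged = True
            break
        step = np.linalg.solve(info, score)
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            cand_dev = _deviance(y, expit(X @ cand))
            if cand_dev <= dev + 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        mu = expit(X @ beta)
        new_dev = _deviance(y, mu)
        if deviance_trace is not None:
            deviance_trace.append(new_dev)
        if abs(dev - new_dev) < dev_tol * (abs(dev) + 1e-12):
            dev = new_dev
            converged = True
            break
        dev = new_dev
    cov = np.linalg.inv(info)
    return beta, cov, converged, dev


def fit_response_logistic(cohort: CohortTable) -> LogisticFit:
    """Logistic regression of treatment response on baseline items, age, gender.

    Gender enters as a male indicator; patients with unknown gender are
    dropped (with a warning).  Raises if the outcome has a single class or
    the design is rank deficient (naming the collinear columns).
    Coefficients whose magnitude exceeds 15 on the log-odds scale flag
    (quasi-)separation, marking the Wald p-values unreliable.
    """
    keep = [r for r in cohort.records if r.gender in ("male", "female")]
    n_dropped = len(cohort) - len(keep)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} patient(s) with unknown gender dropped from the "
            "logistic regression",
            stacklevel=2,
        )
    sub = CohortTable(tuple(keep))
    y = np.array(
        [1.0 if response_status(r.endpoint) == RESPONDER else 0.0 for r in sub]
    )
    if y.size == 0 or len(np.unique(y)) < 2:
        raise ValueError("response outcome must contain both classes")
    names = ["intercept", *ITEM_LABELS, "age", "gender_male"]
    X = np.column_stack(
        [
            np.ones(len(sub)),
            sub.baseline_matrix(),
            sub.ages(),
            np.array([1.0 if r.gender == "male" else 0.0 for r in sub]),
        ]
    )
    if len(sub) <= X.shape[1]:
        raise ValueError(
            f"need more patients ({len(sub)}) than predictors ({X.shape[1]})"
        )
    _check_design_rank(X, names)
    beta, cov, converged, dev = _irls_logistic(X, y)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p_vals = 2.0 * (1.0 - ndtr(np.abs(z)))
    separation = bool(np.any(np.abs(beta) > SEPARATION_BOUND))
    if separation:
        warnings.warn(
            "possible separation: a coefficient exceeds 15 on the log-odds "
            "scale; Wald p-values are unreliable",
            stacklevel=2,
        )
    return LogisticFit(
        predictors=tuple(names),
        coefficients=beta,
        standard_errors=se,
        wald_p_values=p_vals,
        converged=converged,
        separation_flag=separation,
        n_used=len(sub),
        n_dropped=n_dropped,
        deviance=dev,
    )
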