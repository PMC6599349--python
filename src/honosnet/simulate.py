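"""Synthetic paired ordinal cohorts with a known latent network structure.

The generative model is a latent Gaussian copula: each patient carries a
12-dimensional latent normal vector per occasion whose correlation matrix is
implied by a ground-truth partial-correlation network; observed item scores
are obtained by cutting the latent values at per-item thresholds into the
five ordinal categories 0..4.  This is exactly the data-generating family
under which the rank-based SKEPTIC correlation estimator is consistent, so
parameter-recovery tests against the generator's truth are fair.

Clinical improvement between baseline and end point is encoded as a per-item
*latent mean shift* (the thresholds stay fixed), which lowers the observed
ordinal means without touching the conditional-dependence structure.
Follow-up delays are truncated-normal (at one day); age and gender follow a
routine community mental-health cohort profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import ndtr

from .data import CohortTable, ItemProfile, PatientRecord
from .items import (
    N_ITEMS,
    REFERENCE_BASELINE_MEANS,
    REFERENCE_ENDPOINT_MEANS,
)

#: Number of ordinal categories (scores 0..4) and thresholds per item.
N_CATEGORIES = 5
N_THRESHOLDS = N_CATEGORIES - 1

#: Default evenly spaced threshold offsets before the per-item shift; one
#: latent SD between consecutive category cutpoints.
_BASE_OFFSETS = np.array([-1.5, -0.5, 0.5, 1.5])


@dataclass(frozen=True)
class TrueNetworkBundle:
    """Ground truth for one occasion's latent network.

    ``partials`` is the symmetric zero-diagonal matrix of true partial
    correlations; ``sigma`` the implied latent correlation matrix (positive
    definite, unit diagonal); ``thresholds`` the (12, 4) strictly increasing
    cutpoints mapping a latent normal value to ordinal categories.
    """

    partials: np.ndarray
    sigma: np.ndarray
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        partials = np.asarray(self.partials, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        thresholds = np.asarray(self.thresholds, dtype=float)
        p = partials.shape[0]
        if partials.shape != (p, p) or sigma.shape != (p, p):
            raise ValueError("partials and sigma must be square and same size")
        if thresholds.shape != (p, N_THRESHOLDS):
            raise ValueError(f"thresholds must have shape ({p}, {N_THRESHOLDS})")
        if np.any(np.diff(thresholds, axis=1) <= 0):
            raise ValueError("thresholds must be strictly increasing per item")
        if np.min(np.linalg.eigvalsh(sigma)) <= 0:
            raise ValueError("sigma must be positive definite")
        object.__setattr__(self, "partials", partials)
        object.__setattr__(self, "sigma", sigma)
        object.__setattr__(self, "thresholds", thresholds)

    @property
    def n_items(self) -> int:
        return self.partials.shape[0]

    def edge_mask(self, tol: float = 1e-12) -> np.ndarray:
        """Boolean upper-triangle mask of true edges."""
        iu = np.triu_indices(self.n_items, k=1)
        return np.abs(self.partials[iu]) > tol

    def to_jsonable(self) -> dict:
        return {
            "partials": self.partials.tolist(),
            "sigma": self.sigma.tolist(),
            "thresholds": self.thresholds.tolist(),
        }


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation settings.

    Defaults reproduce the reference study conditions: 137 paired patients,
    follow-up delay mean 462.1 days (SD 170.3), and an end-point latent
    improvement calibrated so the per-item ordinal means drop from the
    baseline to the end-point reference profile.
    """

    n_patients: int = 137
    delay_mean: float = 462.1
    delay_sd: float = 170.3
    cross_occasion_latent_correlation: float = 0.3
    improvement_shift: tuple[float, ...] | None = None
    seed: int = 0
    age_mean: float = 41.1
    age_sd: float = 13.7
    age_range: tuple[int, int] = (18, 70)
    prop_male: float = 0.409

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.delay_sd < 0:
            raise ValueError("delay_sd must be >= 0")
        rho = self.cross_occasion_latent_correlation
        if not (0.0 <= rho < 1.0):
            raise ValueError(
                "cross_occasion_latent_correlation must be in [0, 1)"
            )
        if self.improvement_shift is not None:
            shift = tuple(float(s) for s in self.improvement_shift)
            if len(shift) != N_ITEMS:
                raise ValueError(f"improvement_shift needs {N_ITEMS} entries")
            object.__setattr__(self, "improvement_shift", shift)


def implied_ordinal_mean(cutpoints: np.ndarray, latent_mean: float = 0.0) -> float:
    """Mean of the ordinal score when the latent variable is N(latent_mean, 1).

    With score = number of cutpoints below the latent value, the mean is
    ``sum_k P(z > c_k) = sum_k Phi(latent_mean - c_k)``.
    """
    return float(np.sum(ndtr(latent_mean - np.asarray(cutpoints, dtype=float))))


def _solve_threshold_shift(
    target_mean: float, offsets: np.ndarray, tol: float = 1e-10
) -> float:
    """Find t such that cutpoints ``offsets - t`` give the target ordinal mean.

    The implied mean is strictly increasing in t, so plain bisection works.
    """
    lo, hi = -12.0, 12.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if implied_ordinal_mean(offsets - mid) < target_mean:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def default_marginal_thresholds(
    target_means: Sequence[float] = REFERENCE_BASELINE_MEANS,
) -> np.ndarray:
    """Per-item thresholds whose implied ordinal means match the targets.

    Each item's four cutpoints are an evenly spaced template shifted by a
    single per-item offset found by monotone bisection; the implied mean
    under a standard-normal latent matches the target to ~1e-9 (well inside
    the 0.05 calibration requirement).
    """
    targets = np.asarray(target_means, dtype=float)
    if targets.shape != (N_ITEMS,):
        raise ValueError(f"need {N_ITEMS} target means")
    if np.any(targets <= 0.0) or np.any(targets >= float(N_CATEGORIES - 1)):
        raise ValueError("target means must lie strictly inside (0, 4)")
    thresholds = np.empty((N_ITEMS, N_THRESHOLDS))
    for i, m in enumerate(targets):
        t = _solve_threshold_shift(m, _BASE_OFFSETS)
        thresholds[i] = _BASE_OFFSETS - t
    return thresholds


def default_improvement_shift(
    thresholds: np.ndarray,
    endpoint_means: Sequence[float] = REFERENCE_ENDPOINT_MEANS,
) -> np.ndarray:
    """Latent mean decreases reproducing the end-point ordinal mean profile.

    For each item, finds delta >= such that a latent N(-delta, 1) against the
    item's (baseline-calibrated) thresholds yields the end-point target mean.
    """
    targets = np.asarray(endpoint_means, dtype=float)
    shifts = np.empty(N_ITEMS)
    for i in range(N_ITEMS):
        lo, hi = -12.0, 12.0
        cuts = thresholds[i]
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if implied_ordinal_mean(cuts, latent_mean=-mid) > targets[i]:
                lo = mid
            else:
                hi = mid
        shifts[i] = 0.5 * (lo + hi)
    return shifts


def make_true_network(
    p: int = N_ITEMS,
    density: float = 0.15,
    weight_range: tuple[float, float] = (0.2, 0.4),
    seed: int | None = None,
    thresholds: np.ndarray | None = None,
    max_shrink_iter: int = 60,
) -> TrueNetworkBundle:
    """Draw a random sparse ground-truth partial-correlation network.

    Each of the p(p-1)/2 node pairs receives an edge independently with
    probability ``density``; edge weights are uniform in ``weight_range``
    with random sign.  The precision matrix is built with unit diagonal and
    off-diagonal entries ``-w_ij``; if it is not comfortably positive
    definite all weights are shrunk by a fixed factor (0.9) until it is.
    The latent correlation matrix is the rescaled inverse, which leaves the
    partial correlations untouched.
    """
    if p < 2:
        raise ValueError("p must be >= 2")
    if not (0.0 <= density <= 1.0):
        raise ValueError("density must lie in [0, 1]")
    lo, hi = weight_range
    if not (0.0 <= lo <= hi):
        raise ValueError("weight_range must satisfy 0 <= lo <= hi")
    rng = np.random.default_rng(seed)

    iu = np.triu_indices(p, k=1)
    n_pairs = iu[0].size
    present = rng.random(n_pairs) < density
    magnitudes = rng.uniform(lo, hi, size=n_pairs)
    signs = rng.choice([-1.0, 1.0], size=n_pairs)
    weights = np.where(present, signs * magnitudes, 0.0)

    for _ in range(max_shrink_iter):
        omega = np.eye(p)
        omega[iu] = -weights
        omega.T[iu] = -weights
        if np.min(np.linalg.eigvalsh(omega)) > 1e-3:
            break
        weights = weights * 0.9
    else:
        raise ValueError(
            "could not reach a positive-definite precision matrix by "
            f"shrinking weights within {max_shrink_iter} iterations"
        )

    sigma = np.linalg.inv(omega)
    d = np.sqrt(np.diag(sigma))
    sigma = sigma / np.outer(d, d)
    sigma = 0.5 * (sigma + sigma.T)
    np.fill_diagonal(sigma, 1.0)

    partials = np.zeros((p, p))
    partials[iu] = weights
    partials.T[iu] = weights

    if thresholds is None:
        if p == N_ITEMS:
            thresholds = default_marginal_thresholds()
        else:
            thresholds = np.tile(_BASE_OFFSETS, (p, 1))
    return TrueNetworkBundle(partials=partials, sigma=sigma, thresholds=thresholds)


def _symmetric_sqrt(sigma: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(sigma)
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def categorize(latent: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Map latent values (n, p) to ordinal categories via per-item cutpoints."""
    latent = np.atleast_2d(latent)
    n, p = latent.shape
    scores = np.empty((n, p), dtype=int)
    for j in range(p):
        scores[:, j] = np.searchsorted(thresholds[j], latent[:, j])
    return scores


def sample_ordinal_matrix(
    bundle: TrueNetworkBundle,
    n: int,
    rng: np.random.Generator,
    latent_shift: np.ndarray | None = None,
) -> np.ndarray:
    """Sample an (n, p) ordinal score matrix from one occasion's truth."""
    root = _symmetric_sqrt(bundle.sigma)
    latent = rng.standard_normal((n, bundle.n_items)) @ root.T
    if latent_shift is not None:
        latent = latent - np.asarray(latent_shift, dtype=float)
    return categorize(latent, bundle.thresholds)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lower: float
) -> float:
    if sd == 0:
        return max(mean, lower)
    a = (lower - mean) / sd
    return float(stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng))


@dataclass(frozen=True)
class SimTruth:
    """Everything needed to score recovery: both bundles plus the config."""

    baseline: TrueNetworkBundle
    endpoint: TrueNetworkBundle
    config: SimConfig
    improvement_shift: tuple[float, ...] = field(default=())

    def to_jsonable(self) -> dict:
        cfg = self.config
        return {
            "baseline": self.baseline.to_jsonable(),
            "endpoint": self.endpoint.to_jsonable(),
            "improvement_shift": list(self.improvement_shift),
            "config": {
                "n_patients": cfg.n_patients,
                "delay_mean": cfg.delay_mean,
                "delay_sd": cfg.delay_sd,
                "cross_occasion_latent_correlation":
                    cfg.cross_occasion_latent_correlation,
                "seed": cfg.seed,
            },
        }


def sample_ordinal_cohort(
    bundle_base: TrueNetworkBundle,
    bundle_end: TrueNetworkBundle,
    cfg: SimConfig,
) -> tuple[CohortTable, SimTruth]:
    """Draw a full paired cohort from two ground-truth bundles.

    Per patient, a shared latent factor induces the configured cross-occasion
    correlation: with ``u, v`` independent standard normal vectors and
    ``A, B`` the symmetric square roots of the two latent correlation
    matrices, the baseline latent is ``A u`` and the end-point latent is
    ``B (rho u + sqrt(1 - rho^2) v) - shift``.  Both marginals are exact and
    the joint latent covariance is positive definite for any rho in [0, 1).

    A single master seed spawns one independent stream per patient, so the
    cohort is reproducible and insensitive to consumption order.
    """
    if bundle_base.n_items != N_ITEMS or bundle_end.n_items != N_ITEMS:
        raise ValueError(f"both bundles must have p={N_ITEMS}")
    if cfg.improvement_shift is None:
        shift = default_improvement_shift(bundle_base.thresholds)
    else:
        shift = np.asarray(cfg.improvement_shift, dtype=float)

    rho = cfg.cross_occasion_latent_correlation
    root_b = _symmetric_sqrt(bundle_base.sigma)
    root_e = _symmetric_sqrt(bundle_end.sigma)

    master = np.random.SeedSequence(cfg.seed)
    children = master.spawn(cfg.n_patients)
    records = []
    lo_age, hi_age = cfg.age_range
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        u = rng.standard_normal(N_ITEMS)
        v = rng.standard_normal(N_ITEMS)
        z_base = root_b @ u
        z_end = root_e @ (rho * u + np.sqrt(1.0 - rho**2) * v) - shift
        scores_b = categorize(z_base, bundle_base.thresholds)[0]
        scores_e = categorize(z_end, bundle_end.thresholds)[0]
        delay = _truncated_normal(rng, cfg.delay_mean, cfg.delay_sd, lower=1.0)
        age_raw = _truncated_normal(rng, cfg.age_mean, cfg.age_sd, lower=lo_age)
        age = int(np.clip(round(age_raw), lo_age, hi_age))
        gender = "male" if rng.random() < cfg.prop_male else "female"
        records.append(
            PatientRecord(
                patient_id=f"P{i + 1:04d}",
                age=age,
                gender=gender,
                baseline=ItemProfile(tuple(int(s) for s in scores_b)),
                endpoint=ItemProfile(tuple(int(s) for s in scores_e)),
                delay_days=delay,
            )
        )
    truth = SimTruth(
        baseline=bundle_base,
        endpoint=bundle_end,
        config=cfg,
        improvement_shift=tuple(float(s) for s in shift),
    )
    return CohortTable(tuple(records)), truth


def simulate_study_cohort(
    n_patients: int = 137,
    density_base: float = 0.15,
    density_end: float = 0.4,
    weight_range: tuple[float, float] = (0.2, 0.4),
    seed: int = 0,
    **config_kwargs,
) -> tuple[CohortTable, SimTruth]:
    """One-call generator for the default study conditions.

    A sparse baseline truth and a denser end-point truth (sharing the same
    marginal thresholds) emulate a cohort whose symptom network tightens
    over a year of treatment while the individual item scores improve.
    """
    ss = np.random.SeedSequence(seed)
    seed_base, seed_end = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    thresholds = default_marginal_thresholds()
    bundle_base = make_true_network(
        N_ITEMS, density_base, weight_range, seed=seed_base, thresholds=thresholds
    )
    bundle_end = make_true_network(
        N_ITEMS, density_end, weight_range, seed=seed_end, thresholds=thresholds
    )
    cfg = SimConfig(n_patients=n_patients, seed=seed, **config_kwargs)
    return sample_ordinal_cohort(bundle_base, bundle_end, cfg)
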