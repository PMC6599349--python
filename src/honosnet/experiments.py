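"""Simulation studies validating the pipeline against known ground truth.

These are the package's self-checks: type-I error calibration of the
permutation comparison test and the signed-rank test, edge-recovery
operating characteristics of the EBIC-glasso estimator, the power of the
comparison test against a dense alternative, and the qualitative
baseline-vs-end-point connectivity contrast on full synthetic cohorts.
Each function returns plain floats and is deterministic given its seed.

Default problem sizes are chosen to finish in minutes on one CPU while
keeping Monte-Carlo error well inside the tolerance bands they are checked
against (rates over 200+ replicates have a standard error below 0.02).
"""

from __future__ import annotations

import warnings

import numpy as np

from .data import CohortTable
from .estimation import estimate_network
from .metrics import global_strength, nct_global_strength
from .preprocessing import residualize_cohort
from .scores import paired_wilcoxon
from .simulate import (
    SimConfig,
    default_marginal_thresholds,
    make_true_network,
    sample_ordinal_cohort,
    sample_ordinal_matrix,
)

N_ITEMS = 12


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def nct_type1_study(
    n_per_group: int = 100,
    n_permutations: int = 200,
    n_replicates: int = 200,
    alpha: float = 0.05,
    density: float = 0.15,
    weight_range: tuple[float, float] = (0.2, 0.4),
    seed: int = 0,
) -> float:
    """Empirical type-I error of the global-strength permutation test.

    Both groups are drawn from the *same* generative network per replicate,
    so every rejection is a false positive.  Returns the rejection rate at
    ``alpha``.
    """
    seeds = _spawn_seeds(seed, n_replicates)
    rejections = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep_seed in seeds:
            rng = np.random.default_rng(rep_seed)
            bundle = make_true_network(
                N_ITEMS, density, weight_range,
                seed=int(rng.integers(2**31)),
            )
            a = sample_ordinal_matrix(bundle, n_per_group, rng).astype(float)
            b = sample_ordinal_matrix(bundle, n_per_group, rng).astype(float)
            res = nct_global_strength(
                a, b, n_permutations=n_permutations,
                seed=int(rng.integers(2**31)),
            )
            if res.p_value < alpha:
                rejections += 1
    return rejections / n_replicates


def wilcoxon_type1_study(
    n: int = 137,
    n_replicates: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical type-I error of the paired signed-rank test.

    Baseline and end-point scores for a single item are sampled i.i.d.
    from the same ordinal marginal (the reference depressed-mood item), so
    the null of no shift holds exactly.
    """
    from scipy.special import ndtr

    thresholds = default_marginal_thresholds()[6]  # a mid-range item
    probs = np.diff(np.concatenate([[0.0], ndtr(thresholds), [1.0]]))
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        x = rng.choice(5, size=n, p=probs).astype(float)
        y = rng.choice(5, size=n, p=probs).astype(float)
        if paired_wilcoxon(x, y).p_value < alpha:
            rejections += 1
    return rejections / n_replicates


def edge_recovery_study(
    n: int = 1000,
    density: float = 0.15,
    weight_range: tuple[float, float] = (0.2, 0.4),
    n_seeds: int = 20,
    gamma: float = 0.0,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean edge sensitivity and false-positive rate of the estimator.

    Per seed, a sparse truth is drawn, an ordinal sample of size ``n``
    generated, the network estimated at the given ``gamma``, and the
    estimated edge set compared with the truth.  Returns
    ``(sensitivity, false_positive_rate)`` averaged over seeds.
    """
    seeds = _spawn_seeds(seed, n_seeds)
    sens, fpr = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep_seed in seeds:
            rng = np.random.default_rng(rep_seed)
            bundle = make_true_network(
                N_ITEMS, density, weight_range,
                seed=int(rng.integers(2**31)),
            )
            X = sample_ordinal_matrix(bundle, n, rng).astype(float)
            net, _ = estimate_network(X, gamma=gamma)
            true_edges = bundle.edge_mask()
            est_edges = net.edge_mask()
            n_true = int(true_edges.sum())
            n_null = true_edges.size - n_true
            if n_true > 0:
                sens.append(np.sum(est_edges & true_edges) / n_true)
            if n_null > 0:
                fpr.append(np.sum(est_edges & ~true_edges) / n_null)
    return float(np.mean(sens)), float(np.mean(fpr))


def nct_power_study(
    n_per_group: int = 300,
    n_replicates: int = 50,
    n_permutations: int = 200,
    alpha: float = 0.05,
    dense_density: float = 0.4,
    dense_weight_range: tuple[float, float] = (0.3, 0.4),
    seed: int = 0,
) -> float:
    """Power of the comparison test: empty truth vs a dense strong network."""
    seeds = _spawn_seeds(seed, n_replicates)
    thresholds = default_marginal_thresholds()
    rejections = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep_seed in seeds:
            rng = np.random.default_rng(rep_seed)
            empty = make_true_network(
                N_ITEMS, 0.0, (0.0, 0.0), seed=int(rng.integers(2**31)),
                thresholds=thresholds,
            )
            dense = make_true_network(
                N_ITEMS, dense_density, dense_weight_range,
                seed=int(rng.integers(2**31)), thresholds=thresholds,
            )
            a = sample_ordinal_matrix(empty, n_per_group, rng).astype(float)
            b = sample_ordinal_matrix(dense, n_per_group, rng).astype(float)
            res = nct_global_strength(
                a, b, n_permutations=n_permutations,
                seed=int(rng.integers(2**31)),
            )
            if res.p_value < alpha:
                rejections += 1
    return rejections / n_replicates


def connectivity_contrast_study(
    n_patients: int = 137,
    density_base: float = 0.15,
    density_end: float = 0.4,
    weight_range: tuple[float, float] = (0.2, 0.4),
    n_seeds: int = 20,
    n_permutations: int = 400,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Full-pipeline contrast: sparse baseline truth vs dense end-point truth.

    Per seed, a paired cohort is simulated, both occasions residualized on
    the shared delays, networks estimated, and the permutation comparison
    test run.  Returns the fraction of seeds with end-point global strength
    above baseline and the fraction rejecting at ``alpha``.
    """
    seeds = _spawn_seeds(seed, n_seeds)
    thresholds = default_marginal_thresholds()
    gs_greater = 0
    rejected = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep_seed in seeds:
            rng = np.random.default_rng(rep_seed)
            bundle_base = make_true_network(
                N_ITEMS, density_base, weight_range,
                seed=int(rng.integers(2**31)), thresholds=thresholds,
            )
            bundle_end = make_true_network(
                N_ITEMS, density_end, weight_range,
                seed=int(rng.integers(2**31)), thresholds=thresholds,
            )
            cfg = SimConfig(n_patients=n_patients, seed=int(rng.integers(2**31)))
            cohort, _ = sample_ordinal_cohort(bundle_base, bundle_end, cfg)
            res_base, res_end = residualize_cohort(cohort)
            net_base, _ = estimate_network(res_base.values)
            net_end, _ = estimate_network(res_end.values)
            if global_strength(net_end) > global_strength(net_base):
                gs_greater += 1
            nct = nct_global_strength(
                res_base.values, res_end.values,
                n_permutations=n_permutations,
                seed=int(rng.integers(2**31)),
            )
            if nct.p_value < alpha:
                rejected += 1
    return {
        "endpoint_stronger_fraction": gs_greater / n_seeds,
        "reject_fraction": rejected / n_seeds,
    }


def flow_and_response_check() -> dict[str, float]:
    """Arithmetic of the study flow on a deterministically built cohort.

    Builds a 248-patient cohort in which exactly 111 patients are
    non-severe at baseline and, among the 137 severe ones, exactly 82 reach
    the non-severe level at end point; then runs the severity filter and
    the response-proportion computation and reports what they return.
    """
    from .data import ItemProfile, PatientRecord, filter_baseline_severe
    from .scores import response_proportion

    severe = ItemProfile((3,) + (0,) * 11)
    mild = ItemProfile((2,) + (0,) * 11)
    records = []
    k = 0
    for _ in range(111):  # screened out: non-severe at baseline
        records.append(PatientRecord(f"N{k}", 40, "female", mild, mild, 365.0))
        k += 1
    for i in range(137):  # analysed: severe at baseline
        endpoint = mild if i < 82 else severe
        records.append(PatientRecord(f"S{k}", 40, "male", severe, endpoint, 365.0))
        k += 1
    cohort = CohortTable(tuple(records))
    analysed, excluded = filter_baseline_severe(cohort)
    count, proportion = response_proportion(analysed)
    return {
        "screened": float(len(cohort)),
        "excluded": float(excluded),
        "analysed": float(len(analysed)),
        "responders": float(count),
        "responder_percent": 100.0 * proportion,
    }
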