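"""Network-level and node-level metrics, and their inferential machinery.

* **Global strength** — the sum of absolute edge weights over all node
  pairs, the study's measure of overall network connectivity.
* **NCT** — a two-tailed permutation test of the between-sample difference
  in global strength: pooled individuals are repeatedly regrouped into two
  samples of the original sizes and the full estimation pipeline (SKEPTIC +
  EBIC-glasso) is re-run on each regrouping.
* **Node strength centrality** — per-node sum of absolute incident weights,
  reported raw and z-standardized; closeness and betweenness are available
  but secondary (they are rarely stable at clinical sample sizes).
* **Case-drop bootstrap stability** — the CS-coefficient: the largest
  proportion of cases that can be dropped while the subsample centrality
  still correlates >= ``cor_threshold`` with the full-sample centrality in
  >= ``confidence`` of subsamples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .estimation import EDGE_TOL, WeightedNetwork, estimate_network

DEFAULT_DROP_PROPORTIONS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7)

#: Minimum CS-coefficient for a centrality measure to be interpretable.
CS_PASS_THRESHOLD = 0.25


@dataclass(frozen=True)
class NctResult:
    """Permutation network-comparison-test outcome for global strength."""

    observed_difference: float
    permutation_differences: np.ndarray
    p_value: float
    n_permutations: int
    seed: int | None
    n_failed: int = 0
    global_strength_a: float = float("nan")
    global_strength_b: float = float("nan")


@dataclass(frozen=True)
class CentralityReport:
    labels: tuple[str, ...]
    strength: np.ndarray
    strength_z: np.ndarray | None
    closeness: np.ndarray | None = None
    betweenness: np.ndarray | None = None
    degenerate: bool = False


@dataclass(frozen=True)
class StabilityResult:
    """Case-drop bootstrap stability of one centrality measure."""

    measure: str
    cs_coefficient: float
    drop_proportions: tuple[float, ...]
    correlations: dict[float, np.ndarray]
    retain_fractions: dict[float, float]
    passes: bool
    cor_threshold: float
    confidence: float
    seed: int | None


def global_strength(net: WeightedNetwork) -> float:
    """Sum of absolute edge weights over the upper triangle."""
    iu = np.triu_indices(net.p, k=1)
    return float(np.sum(np.abs(net.weights[iu])))


def node_strength(net: WeightedNetwork) -> tuple[np.ndarray, np.ndarray | None]:
    """Per-node strength and its z-standardization across nodes.

    The z-scores are undefined for an all-zero (empty) network; ``None`` is
    returned with a warning in that case.
    """
    s = np.sum(np.abs(net.weights), axis=1)
    sd = s.std(ddof=0)
    if sd == 0.0:
        if np.all(s == 0.0):
            warnings.warn("empty network: strength z-scores undefined",
                          stacklevel=2)
        else:
            warnings.warn("constant node strengths: z-scores undefined",
                          stacklevel=2)
        return s, None
    return s, (s - s.mean()) / sd


def _distance_graph(net: WeightedNetwork) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(range(net.p))
    iu = np.triu_indices(net.p, k=1)
    for i, j in zip(*iu):
        w = abs(net.weights[i, j])
        if w > EDGE_TOL:
            G.add_edge(int(i), int(j), distance=1.0 / w)
    return G


def closeness_betweenness(
    net: WeightedNetwork,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Shortest-path centralities on the |weight|-derived distance graph.

    Edge distances are ``1 / |w|``.  Closeness of a node is the inverse of
    its mean shortest-path distance to the nodes it can reach (disconnected
    pairs are excluded); betweenness is the unnormalized shortest-path
    count.  An empty network yields all zeros with a flag.
    """
    G = _distance_graph(net)
    if G.number_of_edges() == 0:
        return np.zeros(net.p), np.zeros(net.p), True
    closeness = np.zeros(net.p)
    for v in range(net.p):
        lengths = nx.single_source_dijkstra_path_length(G, v, weight="distance")
        dists = [d for u, d in lengths.items() if u != v]
        if dists:
            closeness[v] = 1.0 / float(np.mean(dists))
    btw = nx.betweenness_centrality(G, weight="distance", normalized=False)
    betweenness = np.array([btw[v] for v in range(net.p)])
    return closeness, betweenness, False


def centrality_report(
    net: WeightedNetwork, include_path_measures: bool = False
) -> CentralityReport:
    s, z = node_strength(net)
    closeness = betweenness = None
    degenerate = z is None
    if include_path_measures:
        closeness, betweenness, empty = closeness_betweenness(net)
        degenerate = degenerate or empty
    return CentralityReport(
        labels=net.labels,
        strength=s,
        strength_z=z,
        closeness=closeness,
        betweenness=betweenness,
        degenerate=degenerate,
    )


def _estimated_global_strength(data: np.ndarray, **est_kwargs) -> float:
    net, _ = estimate_network(data, **est_kwargs)
    return global_strength(net)


def nct_global_strength(
    data_a: np.ndarray,
    data_b: np.ndarray,
    n_permutations: int = 1000,
    seed: int | None = None,
    paired: bool = False,
    gamma: float = 0.0,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
) -> NctResult:
    """Permutation test of the global-strength difference between samples.

    The observed statistic is ``|GS(A) - GS(B)|`` with each network
    estimated by the full SKEPTIC + EBIC-glasso pipeline.  Under the
    default (unpaired) scheme all rows are pooled and randomly reassigned
    to two groups of the original sizes per permutation; ``paired=True``
    instead swaps the two occasions within each patient with probability
    1/2 (a methodological variant, off by default).  The p-value uses the
    add-one convention ``(1 + #{perm >= obs}) / (1 + n_perm)``.

    Aborts if estimation fails in more than 5% of permutations.
    """
    A = np.asarray(data_a, dtype=float)
    B = np.asarray(data_b, dtype=float)
    if A.ndim != 2 or B.ndim != 2 or A.shape[1] != B.shape[1]:
        raise ValueError("data_a and data_b must be 2-D with equal column count")
    if A.shape[0] < 3 or B.shape[0] < 3:
        raise ValueError("each sample needs at least 3 rows")
    if paired and A.shape[0] != B.shape[0]:
        raise ValueError("paired permutation requires equal sample sizes")
    est_kwargs = dict(
        gamma=gamma, n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio
    )
    gs_a = _estimated_global_strength(A, **est_kwargs)
    gs_b = _estimated_global_strength(B, **est_kwargs)
    observed = abs(gs_a - gs_b)

    rng = np.random.default_rng(seed)
    n_a = A.shape[0]
    pooled = np.vstack([A, B])
    n_total = pooled.shape[0]
    diffs = np.empty(n_permutations)
    n_failed = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for t in range(n_permutations):
            if paired:
                swap = rng.random(n_a) < 0.5
                pa = np.where(swap[:, None], B, A)
                pb = np.where(swap[:, None], A, B)
            else:
                idx = rng.permutation(n_total)
                pa = pooled[idx[:n_a]]
                pb = pooled[idx[n_a:]]
            try:
                d = abs(
                    _estimated_global_strength(pa, **est_kwargs)
                    - _estimated_global_strength(pb, **est_kwargs)
                )
            except Exception:
                n_failed += 1
                diffs[t] = np.nan
                continue
            diffs[t] = d
    if n_failed > 0.05 * n_permutations:
        raise RuntimeError(
            f"network estimation failed in {n_failed}/{n_permutations} "
            "permutations; the comparison is unreliable"
        )
    valid = diffs[~np.isnan(diffs)]
    p = (1.0 + float(np.sum(valid >= observed - 1e-15))) / (1.0 + valid.size)
    return NctResult(
        observed_difference=observed,
        permutation_differences=valid,
        p_value=p,
        n_permutations=int(valid.size),
        seed=seed,
        n_failed=n_failed,
        global_strength_a=gs_a,
        global_strength_b=gs_b,
    )


def _centrality_vector(net: WeightedNetwork, measure: str) -> np.ndarray:
    if measure == "strength":
        return np.sum(np.abs(net.weights), axis=1)
    closeness, betweenness, _ = closeness_betweenness(net)
    if measure == "closeness":
        return closeness
    if measure == "betweenness":
        return betweenness
    raise ValueError(f"unknown centrality measure {measure!r}")


def cs_from_correlations(
    correlations: dict[float, np.ndarray],
    cor_threshold: float,
    confidence: float,
) -> tuple[float, dict[float, float]]:
    """CS-coefficient from stored per-subsample correlations.

    Returns the largest drop proportion whose retain fraction (share of
    subsamples with correlation >= threshold) reaches the confidence level,
    plus the per-proportion retain fractions.
    """
    retain = {
        prop: float(np.mean(np.asarray(cors) >= cor_threshold))
        for prop, cors in correlations.items()
    }
    cs = 0.0
    for prop in sorted(retain):
        if retain[prop] >= confidence:
            cs = max(cs, prop)
    return cs, retain


def casedrop_stability(
    data: np.ndarray,
    measure: str = "strength",
    n_boots: int = 1000,
    drop_proportions: tuple[float, ...] = DEFAULT_DROP_PROPORTIONS,
    cor_threshold: float = 0.7,
    confidence: float = 0.95,
    seed: int | None = None,
    gamma: float = 0.0,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
) -> StabilityResult:
    """Case-drop bootstrap stability of a centrality measure.

    Per drop proportion, ``n_boots`` subsamples are drawn without
    replacement, the network and centrality re-estimated, and the Pearson
    correlation with the full-sample centrality recorded (degenerate
    constant centralities count as correlation 0).  A measure passes when
    its CS-coefficient reaches 0.25.
    """
    X = np.asarray(data, dtype=float)
    n = X.shape[0]
    max_drop = max(drop_proportions)
    if int(np.floor(n * (1.0 - max_drop))) < 13:
        raise ValueError(
            f"n={n} too small: dropping {max_drop:.0%} leaves fewer than 13 rows"
        )
    est_kwargs = dict(
        gamma=gamma, n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full_net, _ = estimate_network(X, **est_kwargs)
        c_full = _centrality_vector(full_net, measure)
        rng = np.random.default_rng(seed)
        correlations: dict[float, np.ndarray] = {}
        for prop in drop_proportions:
            keep = int(np.floor(n * (1.0 - prop)))
            cors = np.empty(n_boots)
            for b in range(n_boots):
                idx = rng.choice(n, size=keep, replace=False)
                sub_net, _ = estimate_network(X[idx], **est_kwargs)
                c_sub = _centrality_vector(sub_net, measure)
                if c_sub.std() == 0.0 or c_full.std() == 0.0:
                    cors[b] = 0.0
                else:
                    cors[b] = float(np.corrcoef(c_full, c_sub)[0, 1])
            correlations[prop] = cors
    cs, retain = cs_from_correlations(correlations, cor_threshold, confidence)
    return StabilityResult(
        measure=measure,
        cs_coefficient=cs,
        drop_proportions=tuple(drop_proportions),
        correlations=correlations,
        retain_fractions=retain,
        passes=cs >= CS_PASS_THRESHOLD,
        cor_threshold=cor_threshold,
        confidence=confidence,
        seed=seed,
    )
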