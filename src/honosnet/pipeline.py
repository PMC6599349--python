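"""End-to-end orchestration of the two-arm outcome analysis.

Stages, in order: baseline severity filter -> individual-scores arm
(per-item signed-rank tests, response proportion, logistic regression) ->
delay residualization -> per-occasion network estimation -> permutation
comparison of global strength -> centrality and its case-drop stability.
A single seed drives every stochastic stage (each stage gets its own
spawned stream), so identical config + seed gives byte-identical reports.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .data import CohortTable, filter_baseline_severe
from .estimation import estimate_network
from .items import ITEM_LABELS
from .metrics import (
    casedrop_stability,
    centrality_report,
    global_strength,
    nct_global_strength,
)
from .preprocessing import residualize_cohort
from .scores import cohort_wilcoxon, fit_response_logistic, response_proportion

logger = logging.getLogger("honosnet")

REPORT_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A stage failed; the stage name is carried for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings for one full analysis run."""

    gamma: float = 0.0
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    n_permutations: int = 1000
    paired_permutations: bool = False
    n_boots: int = 1000
    stability_measures: tuple[str, ...] = ("strength",)
    cor_threshold: float = 0.7
    confidence: float = 0.95
    residualize_baseline: bool = True
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.gamma < 0 or self.n_lambda < 2:
            raise ValueError("gamma must be >= 0 and n_lambda >= 2")
        if not (0 < self.lambda_min_ratio < 1):
            raise ValueError("lambda_min_ratio must be in (0, 1)")
        if self.n_permutations < 1 or self.n_boots < 1:
            raise ValueError("permutation and bootstrap counts must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "stability_measures" in raw:
            raw["stability_measures"] = tuple(raw["stability_measures"])
        return cls(**raw)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_full_analysis(
    cohort: CohortTable, config: AnalysisConfig | None = None
) -> dict:
    """Run the complete two-arm analysis and return the report dict.

    If ``config.output_dir`` is set, a JSON report plus per-stage CSVs are
    written there; outputs produced before a failing stage are retained.
    """
    config = config or AnalysisConfig()
    out = Path(config.output_dir) if config.output_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    # the config echo excludes the output path so that identical analyses
    # written to different directories produce byte-identical reports
    config_echo = {k: v for k, v in vars(config).items() if k != "output_dir"}
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "config": _jsonable(config_echo),
        "stages": {},
    }
    seed_seq = np.random.SeedSequence(config.seed)
    nct_seed, *stab_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(5)
    ]

    def _save() -> None:
        if out is not None:
            text = json.dumps(report, indent=2, sort_keys=True)
            (out / "report.json").write_text(text + "\n", encoding="utf-8")

    # 1. severity filter
    stage = "severity_filter"
    analysed, excluded = filter_baseline_severe(cohort)
    report["stages"][stage] = {
        "n_screened": len(cohort),
        "n_excluded_non_severe": excluded,
        "n_analysed": len(analysed),
    }
    logger.info("%s: %d screened, %d excluded, %d analysed",
                stage, len(cohort), excluded, len(analysed))
    if len(analysed) < 3:
        _save()
        raise PipelineError(
            stage,
            f"only {len(analysed)} patient(s) meet the baseline severity "
            "criterion; nothing to analyse",
        )

    # 2. individual-scores arm
    stage = "individual_scores"
    base = analysed.baseline_matrix()
    end = analysed.endpoint_matrix()
    wil = cohort_wilcoxon(analysed)
    count, proportion = response_proportion(analysed)
    try:
        logistic = fit_response_logistic(analysed)
        logistic_block = {
            "predictors": list(logistic.predictors),
            "coefficients": logistic.coefficients,
            "standard_errors": logistic.standard_errors,
            "wald_p_values": logistic.wald_p_values,
            "converged": logistic.converged,
            "separation_flag": logistic.separation_flag,
            "n_used": logistic.n_used,
            "n_dropped": logistic.n_dropped,
        }
    except ValueError as exc:
        logistic_block = {"error": str(exc)}
    report["stages"][stage] = _jsonable({
        "items": [
            {
                "item": w.item,
                "baseline_mean": base[:, j].mean(),
                "baseline_sd": base[:, j].std(ddof=1),
                "endpoint_mean": end[:, j].mean(),
                "endpoint_sd": end[:, j].std(ddof=1),
                "V": w.V,
                "p_value": w.p_value,
                "n_effective": w.n_effective,
                "method": w.method,
            }
            for j, w in enumerate(wil)
        ],
        "n_responders": count,
        "response_proportion": proportion,
        "logistic": logistic_block,
    })

    # 3. residualization
    stage = "residualization"
    try:
        res_base, res_end = residualize_cohort(analysed)
    except ValueError as exc:
        _save()
        raise PipelineError(stage, str(exc)) from exc
    if not config.residualize_baseline:
        res_base_values = base - base.mean(axis=0)
    else:
        res_base_values = res_base.values
    from scipy import stats as _st

    t_stats = _st.ttest_rel(res_base_values, res_end.values).statistic
    report["stages"][stage] = _jsonable({
        "baseline_column_mean_max_abs": float(
            np.max(np.abs(res_base_values.mean(axis=0)))
        ),
        "endpoint_column_mean_max_abs": float(
            np.max(np.abs(res_end.values.mean(axis=0)))
        ),
        "paired_t_max_abs": float(np.nanmax(np.abs(t_stats))),
    })

    # 4. network estimation per occasion
    stage = "network_estimation"
    est_kwargs = dict(
        gamma=config.gamma,
        n_lambda=config.n_lambda,
        lambda_min_ratio=config.lambda_min_ratio,
    )
    try:
        net_base, fit_base = estimate_network(res_base_values, **est_kwargs)
        net_end, fit_end = estimate_network(res_end.values, **est_kwargs)
    except Exception as exc:
        _save()
        raise PipelineError(stage, str(exc)) from exc
    report["stages"][stage] = _jsonable({
        occ: {
            "weights": net.weights,
            "labels": list(net.labels),
            "edge_count": net.edge_count,
            "global_strength": global_strength(net),
            "selected_lambda": fit.selected_lambda,
            "gamma": fit.gamma,
        }
        for occ, net, fit in (
            ("baseline", net_base, fit_base),
            ("endpoint", net_end, fit_end),
        )
    })
    if out is not None:
        import pandas as pd

        for occ, net in (("baseline", net_base), ("endpoint", net_end)):
            pd.DataFrame(
                net.weights, index=ITEM_LABELS, columns=ITEM_LABELS
            ).to_csv(out / f"network_{occ}.csv")

    # 5. comparison test
    stage = "network_comparison"
    try:
        nct = nct_global_strength(
            res_base_values,
            res_end.values,
            n_permutations=config.n_permutations,
            seed=nct_seed,
            paired=config.paired_permutations,
            **est_kwargs,
        )
    except Exception as exc:
        _save()
        raise PipelineError(stage, str(exc)) from exc
    report["stages"][stage] = _jsonable({
        "observed_difference": nct.observed_difference,
        "p_value": nct.p_value,
        "n_permutations": nct.n_permutations,
        "seed": nct.seed,
        "global_strength_baseline": nct.global_strength_a,
        "global_strength_endpoint": nct.global_strength_b,
    })

    # 6. centrality and stability
    stage = "centrality_stability"
    cent = {}
    for occ, net in (("baseline", net_base), ("endpoint", net_end)):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = centrality_report(net, include_path_measures=True)
        cent[occ] = {
            "strength": rep.strength,
            "strength_z": rep.strength_z,
            "closeness": rep.closeness,
            "betweenness": rep.betweenness,
            "degenerate": rep.degenerate,
        }
    stability = {}
    for i, (occ, values) in enumerate(
        (("baseline", res_base_values), ("endpoint", res_end.values))
    ):
        try:
            stab = casedrop_stability(
                values,
                measure="strength",
                n_boots=config.n_boots,
                cor_threshold=config.cor_threshold,
                confidence=config.confidence,
                seed=stab_seeds[i],
                **est_kwargs,
            )
            stability[occ] = {
                "measure": stab.measure,
                "cs_coefficient": stab.cs_coefficient,
                "retain_fractions": stab.retain_fractions,
                "passes": stab.passes,
                "n_boots": config.n_boots,
                "seed": stab.seed,
            }
        except ValueError as exc:
            stability[occ] = {"error": str(exc)}
    report["stages"][stage] = _jsonable(
        {"centrality": cent, "stability": stability}
    )
    _save()
    return report
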