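"""Delay residualization ahead of network estimation.

Follow-up intervals vary between patients, and scores generally improve over
time, which narrows their range and distorts between-item correlations.  To
neutralize this, each item is regressed (ordinary least squares, intercept +
delay) on the between-rating delay, separately per occasion, and the
residuals replace the raw scores.  OLS residuals have exactly zero mean per
item, so paired t statistics comparing baseline and end-point residuals are
numerically zero — the intended sanity check of the procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import CohortTable
from .items import ITEM_LABELS, N_ITEMS


@dataclass(frozen=True)
class ResidualMatrix:
    """Per-occasion residual scores, one column per item (column means 0)."""

    values: np.ndarray
    occasion: str
    item_labels: tuple[str, ...] = ITEM_LABELS

    @property
    def n(self) -> int:
        return self.values.shape[0]


def residualize_on_delay(
    scores: np.ndarray,
    delays: np.ndarray,
    occasion: str = "",
) -> ResidualMatrix:
    """OLS-residualize an (n, 12) score matrix on the delay vector.

    Fits score ~ intercept + delay per item.  If all delays are identical
    the slope is undefined and the residuals fall back to simple centering
    (with a warning); constant item columns yield all-zero residuals.
    """
    scores = np.asarray(scores, dtype=float)
    delays = np.asarray(delays, dtype=float)
    n = scores.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 patients to residualize, got {n}")
    if scores.shape != (n, N_ITEMS):
        raise ValueError(f"scores must be (n, {N_ITEMS}), got {scores.shape}")
    if delays.shape != (n,):
        raise ValueError("delays must be a length-n vector")

    if np.ptp(delays) == 0.0:
        warnings.warn(
            "all delays identical; falling back to column centering",
            stacklevel=2,
        )
        residuals = scores - scores.mean(axis=0)
    else:
        X = np.column_stack([np.ones(n), delays])
        coef, *_ = np.linalg.lstsq(X, scores, rcond=None)
        residuals = scores - X @ coef

    constant = np.ptp(scores, axis=0) == 0.0
    if np.any(constant):
        labels = [ITEM_LABELS[i] for i in np.flatnonzero(constant)]
        warnings.warn(
            f"constant item column(s) {labels}: residuals are all zero",
            stacklevel=2,
        )
    return ResidualMatrix(values=residuals, occasion=occasion)


def residualize_cohort(
    cohort: CohortTable,
) -> tuple[ResidualMatrix, ResidualMatrix]:
    """Residualize baseline and end-point matrices on the shared delays."""
    delays = cohort.delays()
    base = residualize_on_delay(cohort.baseline_matrix(), delays, "baseline")
    end = residualize_on_delay(cohort.endpoint_matrix(), delays, "endpoint")
    return base, end
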