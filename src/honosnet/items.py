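"""Canonical HoNOS item set.

The Health of the Nation Outcome Scales (HoNOS) comprise 12 clinician-rated
items, each scored on a five-point ordinal severity scale (0 = no problem to
4 = severe/very severe).  The item order below is fixed and used identically
throughout the package: score vectors, correlation matrices, network weight
matrices and centrality reports are all indexed in this order.
"""

from __future__ import annotations

#: Short node labels, in canonical order.
ITEM_LABELS: tuple[str, ...] = (
    "Agi", "S/h", "Sub", "Cog", "Phy", "Hal",
    "Dep", "Oth", "Rel", "ADL", "Liv", "Occ",
)

#: Full item descriptions keyed by short label.
ITEM_DESCRIPTIONS: dict[str, str] = {
    "Agi": "Overactive, aggressive, disruptive or agitated behaviour",
    "S/h": "Non-accidental self-injury",
    "Sub": "Problem drinking or drug-taking",
    "Cog": "Cognitive problems",
    "Phy": "Physical illness or disability problems",
    "Hal": "Problems associated with hallucinations and delusions",
    "Dep": "Problems with depressed mood",
    "Oth": "Other mental and behavioural problems",
    "Rel": "Problems with relationships",
    "ADL": "Problems with activities of daily living",
    "Liv": "Problems with living conditions",
    "Occ": "Problems with occupation and activities",
}

N_ITEMS: int = 12

#: Ordinal rating range (inclusive).
SCORE_MIN: int = 0
SCORE_MAX: int = 4

#: Reference per-item mean scores for a routine community mental-health
#: cohort at service entry (baseline) and after roughly one year of
#: treatment (end point).  These are the default marginal targets of the
#: synthetic-cohort generator.
REFERENCE_BASELINE_MEANS: tuple[float, ...] = (
    0.87, 0.69, 0.53, 0.61, 0.76, 1.01, 1.68, 1.96, 1.58, 0.99, 0.33, 0.92,
)
REFERENCE_ENDPOINT_MEANS: tuple[float, ...] = (
    0.32, 0.33, 0.20, 0.30, 0.80, 0.48, 1.01, 1.61, 1.01, 0.77, 0.23, 0.51,
)
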