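"""Cohort data model: item profiles, paired patient records, severity rules.

A cohort is a collection of patients each rated twice on the 12 HoNOS items
(baseline and end point), together with age, gender and the delay in days
between the two ratings.  Severity follows the individual-item rule used in
routine outcome measurement: a profile is *severe* iff at least one item is
rated 3 or above, and *treatment response* means reaching the non-severe
level at end point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .items import ITEM_LABELS, N_ITEMS, SCORE_MAX, SCORE_MIN

SEVERE = "severe"
NON_SEVERE = "non-severe"

GENDER_LEVELS = ("male", "female", "unknown")

#: Accepted spellings for the explicit other/unknown gender level.
_GENDER_ALIASES = {
    "male": "male", "m": "male",
    "female": "female", "f": "female",
    "other": "unknown", "unknown": "unknown", "u": "unknown",
    "na": "unknown", "": "unknown",
}


class CohortFormatError(ValueError):
    """The input table is structurally unusable (e.g. a missing column)."""


class CohortValidationError(ValueError):
    """A row or value violates the cohort data model."""


def normalize_gender(value: object) -> str:
    key = str(value).strip().lower()
    if key in _GENDER_ALIASES:
        return _GENDER_ALIASES[key]
    raise CohortValidationError(f"unrecognized gender value {value!r}")


@dataclass(frozen=True)
class ItemProfile:
    """One occasion's 12 ordinal item ratings, in canonical item order."""

    scores: tuple[int, ...]

    def __post_init__(self) -> None:
        scores = tuple(int(s) for s in self.scores)
        if len(scores) != N_ITEMS:
            raise CohortValidationError(
                f"expected {N_ITEMS} item scores, got {len(scores)}"
            )
        for label, s in zip(ITEM_LABELS, scores):
            if not (SCORE_MIN <= s <= SCORE_MAX):
                raise CohortValidationError(
                    f"item {label!r} score {s} outside [{SCORE_MIN}, {SCORE_MAX}]"
                )
        object.__setattr__(self, "scores", scores)

    @classmethod
    def from_iterable(cls, values: Iterable[object]) -> "ItemProfile":
        return cls(tuple(int(v) for v in values))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.scores, dtype=float)

    def max(self) -> int:
        return max(self.scores)


@dataclass(frozen=True)
class PatientRecord:
    """Complete paired observation for one patient."""

    patient_id: str
    age: int
    gender: str
    baseline: ItemProfile
    endpoint: ItemProfile
    delay_days: float

    def __post_init__(self) -> None:
        if self.delay_days <= 0:
            raise CohortValidationError(
                f"patient {self.patient_id!r}: delay_days must be > 0, "
                f"got {self.delay_days}"
            )
        if self.age <= 0:
            raise CohortValidationError(
                f"patient {self.patient_id!r}: age must be > 0, got {self.age}"
            )
        if self.gender not in GENDER_LEVELS:
            object.__setattr__(self, "gender", normalize_gender(self.gender))


@dataclass(frozen=True)
class CohortTable:
    """An ordered collection of paired patient records."""

    records: tuple[PatientRecord, ...]
    item_labels: tuple[str, ...] = field(default=ITEM_LABELS)

    def __post_init__(self) -> None:
        records = tuple(self.records)
        object.__setattr__(self, "records", records)
        ids = [r.patient_id for r in records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate patient ids: {dupes}")
        if tuple(self.item_labels) != ITEM_LABELS:
            raise CohortValidationError("item labels must match the canonical order")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def baseline_matrix(self) -> np.ndarray:
        """(n, 12) float array of baseline scores."""
        return np.array([r.baseline.scores for r in self.records], dtype=float)

    def endpoint_matrix(self) -> np.ndarray:
        """(n, 12) float array of end-point scores."""
        return np.array([r.endpoint.scores for r in self.records], dtype=float)

    def delays(self) -> np.ndarray:
        return np.array([r.delay_days for r in self.records], dtype=float)

    def ages(self) -> np.ndarray:
        return np.array([r.age for r in self.records], dtype=float)

    def genders(self) -> tuple[str, ...]:
        return tuple(r.gender for r in self.records)


def classify_severity(profile: ItemProfile) -> str:
    """Severity of one profile: ``severe`` iff any item is rated 3 or above."""
    return SEVERE if profile.max() >= 3 else NON_SEVERE


def is_severe(profile: ItemProfile) -> bool:
    return classify_severity(profile) == SEVERE


def filter_baseline_severe(cohort: CohortTable) -> tuple[CohortTable, int]:
    """Keep only patients who meet the severity criterion at baseline.

    Returns the filtered cohort and the number of excluded patients.  An
    empty result is legal (a warning is emitted) so callers can decide how
    to proceed.
    """
    kept = tuple(r for r in cohort.records if is_severe(r.baseline))
    excluded = len(cohort) - len(kept)
    if not kept:
        warnings.warn(
            "no patient meets the baseline severity criterion", stacklevel=2
        )
    return CohortTable(kept), excluded


def make_cohort(records: Sequence[PatientRecord]) -> CohortTable:
    """Convenience constructor preserving input order."""
    return CohortTable(tuple(records))
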