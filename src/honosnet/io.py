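"""CSV input/output for cohort tables.

The on-disk format is a long/wide hybrid: one row per patient per occasion
(``baseline`` or ``endpoint``), with the patient's id, age, gender and the
between-rating delay repeated on both rows, plus the 12 item score columns.
Column names are configurable through a small YAML mapping; the defaults are
``patient_id, occasion, delay_days, age, gender, item_1 .. item_12``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import (
    CohortFormatError,
    CohortTable,
    CohortValidationError,
    ItemProfile,
    PatientRecord,
    normalize_gender,
)
from .items import N_ITEMS, SCORE_MAX, SCORE_MIN

OCCASION_BASELINE = "baseline"
OCCASION_ENDPOINT = "endpoint"


@dataclass(frozen=True)
class CsvColumns:
    """Column-name mapping for cohort CSV files."""

    patient_id: str = "patient_id"
    occasion: str = "occasion"
    delay_days: str = "delay_days"
    age: str = "age"
    gender: str = "gender"
    items: tuple[str, ...] = field(
        default=tuple(f"item_{i}" for i in range(1, N_ITEMS + 1))
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        if len(self.items) != N_ITEMS:
            raise CohortFormatError(f"need {N_ITEMS} item columns")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CsvColumns":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("patient_id", "occasion", "delay_days", "age", "gender"):
            if key in raw:
                kwargs[key] = str(raw[key])
        if "items" in raw:
            kwargs["items"] = tuple(str(c) for c in raw["items"])
        return cls(**kwargs)


def _parse_occasion_row(
    row: pd.Series, columns: CsvColumns, row_no: int
) -> tuple[ItemProfile, float]:
    scores = []
    for col in columns.items:
        value = row[col]
        if pd.isna(value):
            raise CohortValidationError(
                f"row {row_no}: missing score in column {col!r}"
            )
        score = float(value)
        if score != int(score) or not (SCORE_MIN <= score <= SCORE_MAX):
            raise CohortValidationError(
                f"row {row_no}: column {col!r} has score {value!r} outside "
                f"the integer range [{SCORE_MIN}, {SCORE_MAX}]"
            )
        scores.append(int(score))
    delay = float(row[columns.delay_days])
    return ItemProfile(tuple(scores)), delay


def read_cohort_csv(
    path: str | Path, columns: CsvColumns | None = None
) -> CohortTable:
    """Read a cohort CSV into a :class:`CohortTable`.

    Patients lacking either occasion, or with unparseable rows, are excluded
    complete-case with a warning naming the patient.  Hard violations of the
    format (missing columns) or of the data model on otherwise usable rows
    (scores outside 0..4, mismatched delays within a patient) raise.
    """
    columns = columns or CsvColumns()
    frame = pd.read_csv(path)
    required = [
        columns.patient_id, columns.occasion, columns.delay_days,
        columns.age, columns.gender, *columns.items,
    ]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise CohortFormatError(f"missing column(s) in {path}: {missing}")

    records: list[PatientRecord] = []
    for pid, group in frame.groupby(columns.patient_id, sort=False):
        occ = {}
        for row_no, row in group.iterrows():
            label = str(row[columns.occasion]).strip().lower()
            if label not in (OCCASION_BASELINE, OCCASION_ENDPOINT):
                raise CohortValidationError(
                    f"row {row_no}: occasion must be "
                    f"'{OCCASION_BASELINE}' or '{OCCASION_ENDPOINT}', got {label!r}"
                )
            if label in occ:
                raise CohortValidationError(
                    f"patient {pid!r}: duplicate {label} occasion (row {row_no})"
                )
            occ[label] = (row, row_no)
        if set(occ) != {OCCASION_BASELINE, OCCASION_ENDPOINT}:
            warnings.warn(
                f"patient {pid!r} excluded: only one occasion present",
                stacklevel=2,
            )
            continue
        has_missing = False
        for row, _ in occ.values():
            if any(pd.isna(row[c]) for c in columns.items):
                warnings.warn(
                    f"patient {pid!r} excluded: missing item score(s)",
                    stacklevel=2,
                )
                has_missing = True
                break
        if has_missing:
            continue
        (b_row, b_no) = occ[OCCASION_BASELINE]
        (e_row, e_no) = occ[OCCASION_ENDPOINT]
        baseline, delay_b = _parse_occasion_row(b_row, columns, b_no)
        endpoint, delay_e = _parse_occasion_row(e_row, columns, e_no)
        if not np.isclose(delay_b, delay_e):
            raise CohortValidationError(
                f"patient {pid!r}: delay differs between occasions "
                f"({delay_b} vs {delay_e})"
            )
        records.append(
            PatientRecord(
                patient_id=str(pid),
                age=int(b_row[columns.age]),
                gender=normalize_gender(b_row[columns.gender]),
                baseline=baseline,
                endpoint=endpoint,
                delay_days=delay_b,
            )
        )
    return CohortTable(tuple(records))


def cohort_to_frame(
    cohort: CohortTable, columns: CsvColumns | None = None
) -> pd.DataFrame:
    columns = columns or CsvColumns()
    rows = []
    for record in cohort:
        for occasion, profile in (
            (OCCASION_BASELINE, record.baseline),
            (OCCASION_ENDPOINT, record.endpoint),
        ):
            row = {
                columns.patient_id: record.patient_id,
                columns.occasion: occasion,
                columns.delay_days: record.delay_days,
                columns.age: record.age,
                columns.gender: record.gender,
            }
            row.update(dict(zip(columns.items, profile.scores)))
            rows.append(row)
    return pd.DataFrame(rows)


def write_cohort_csv(
    cohort: CohortTable, path: str | Path, columns: CsvColumns | None = None
) -> None:
    cohort_to_frame(cohort, columns).to_csv(path, index=False)
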