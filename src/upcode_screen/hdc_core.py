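"""Domain types, I/O and cohort extraction for hospital discharge charts.

A Hospital Discharge Chart (HDC) is the administrative record of one
hospitalization: the pseudonymous patient, the provider, admission and
discharge dates, the coded diagnoses and procedures, the DRG assigned by
the grouper, and the reimbursed cost.  DRG assignment itself is out of
scope here — the DRG code is an input field.

The cohort-extraction rule implemented is: a patient *qualifies* when at
least one of their in-window HDCs carries an index-disease diagnosis code
(prefix match, any diagnosis position); all in-window HDCs of qualifying
patients are retained, disease-related or not, so that downstream
specialization ratios have a meaningful denominator.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

__all__ = [
    "HDCRecord",
    "CohortConfig",
    "Cohort",
    "SchemaError",
    "RowValidationError",
    "read_hdc",
    "write_hdc",
    "load_schema",
    "extract_cohort",
    "records_to_frame",
    "save_cohort",
    "load_cohort",
]

OWNERSHIP_VALUES = ("public", "private")

#: field -> CSV column mapping used when no schema is given; list-valued
#: fields are serialized joined by ``;``.
DEFAULT_SCHEMA: dict[str, str] = {
    "event_id": "event_id",
    "patient_id": "patient_id",
    "hospital_id": "hospital_id",
    "admission_date": "admission_date",
    "discharge_date": "discharge_date",
    "age": "age",
    "diagnosis_codes": "diagnosis_codes",
    "procedure_codes": "procedure_codes",
    "drg_code": "drg_code",
    "cost": "cost",
    "ownership": "ownership",
}

LIST_SEP = ";"


class SchemaError(ValueError):
    """A mandatory column is missing or the column mapping is invalid."""


class RowValidationError(ValueError):
    """One or more data rows failed validation.

    Carries ``errors``, a list of ``(row_number, message)`` pairs with
    1-based row numbers counted from the first data row.
    """

    def __init__(self, errors: Sequence[tuple[int, str]]):
        self.errors = list(errors)
        head = "; ".join(f"row {r}: {m}" for r, m in self.errors[:5])
        more = "" if len(self.errors) <= 5 else f" (+{len(self.errors) - 5} more)"
        super().__init__(f"{len(self.errors)} invalid row(s): {head}{more}")


@dataclass(frozen=True)
class HDCRecord:
    """One hospitalization event."""

    event_id: str
    patient_id: str
    hospital_id: str
    admission_date: date
    discharge_date: date
    age: int
    diagnosis_codes: tuple[str, ...]
    procedure_codes: tuple[str, ...]
    drg_code: str
    cost: float
    ownership: str

    def __post_init__(self) -> None:
        if self.discharge_date < self.admission_date:
            raise ValueError(
                f"event {self.event_id}: discharge_date {self.discharge_date} "
                f"before admission_date {self.admission_date}"
            )
        if not self.diagnosis_codes:
            raise ValueError(f"event {self.event_id}: diagnosis_codes empty")
        if self.age < 0:
            raise ValueError(f"event {self.event_id}: age {self.age} < 0")
        if self.cost < 0:
            raise ValueError(f"event {self.event_id}: cost {self.cost} < 0")
        if self.ownership not in OWNERSHIP_VALUES:
            raise ValueError(
                f"event {self.event_id}: ownership {self.ownership!r} not in "
                f"{OWNERSHIP_VALUES}"
            )

    @property
    def los(self) -> int:
        """Length of stay in whole days (same-day discharge gives 0)."""
        return (self.discharge_date - self.admission_date).days


class CohortConfig(BaseModel):
    """Definition of the index disease, its DRG family, and the time window.

    ``disease_codes`` are diagnosis-code *prefixes* (e.g. ``"428"`` captures
    all heart-failure subcodes); the coding system is a configuration
    concern, never hardcoded.  ``cc_drg_codes`` is the "with complications"
    subset of ``drg_family``.  Window membership is judged on the admission
    date, inclusive on both ends.
    """

    model_config = ConfigDict(frozen=True)

    disease_codes: frozenset[str]
    drg_family: frozenset[str]
    cc_drg_codes: frozenset[str]
    window_start: date
    window_end: date

    @field_validator("disease_codes", "drg_family")
    @classmethod
    def _non_empty(cls, v: frozenset[str]) -> frozenset[str]:
        if not v:
            raise ValueError("must be non-empty")
        return v

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        if not self.cc_drg_codes <= self.drg_family:
            raise ValueError("cc_drg_codes must be a subset of drg_family")
        if not self.window_start < self.window_end:
            raise ValueError("window_start must precede window_end")
        return self

    @property
    def drg_family_ordered(self) -> tuple[str, ...]:
        """Deterministic (sorted) DRG family order used for r vectors."""
        return tuple(sorted(self.drg_family))

    def matches_disease(self, diagnosis_codes: Iterable[str]) -> bool:
        return any(
            code.startswith(prefix)
            for code in diagnosis_codes
            for prefix in self.disease_codes
        )


@dataclass(frozen=True)
class Cohort:
    """All in-window hospitalizations of the qualifying patients."""

    records: tuple[HDCRecord, ...]
    qualifying_patient_ids: frozenset[str]
    config: CohortConfig

    def __post_init__(self) -> None:
        extra = {r.patient_id for r in self.records} - self.qualifying_patient_ids
        if extra:
            raise ValueError(f"records of non-qualifying patients: {sorted(extra)[:5]}")


def load_schema(source: str | Path | Mapping[str, str] | None) -> dict[str, str]:
    """Resolve a column-mapping schema from a mapping or a YAML/JSON file.

    The schema maps record field names to CSV column names; fields absent
    from the mapping fall back to their default column name.
    """
    if source is None:
        return dict(DEFAULT_SCHEMA)
    if isinstance(source, Mapping):
        mapping = dict(source)
    else:
        with open(source) as fh:
            mapping = yaml.safe_load(fh)
        if not isinstance(mapping, Mapping):
            raise SchemaError(f"schema file {source} does not contain a mapping")
        mapping = dict(mapping)
    unknown = set(mapping) - set(DEFAULT_SCHEMA)
    if unknown:
        raise SchemaError(f"unknown schema fields: {sorted(unknown)}")
    return {**DEFAULT_SCHEMA, **mapping}


def _parse_row(row: Mapping[str, str], schema: Mapping[str, str]) -> HDCRecord:
    def get(fieldname: str) -> str:
        return row[schema[fieldname]].strip()

    diagnosis = tuple(c.strip() for c in get("diagnosis_codes").split(LIST_SEP) if c.strip())
    proc_raw = get("procedure_codes")
    procedures = tuple(c.strip() for c in proc_raw.split(LIST_SEP) if c.strip())
    return HDCRecord(
        event_id=get("event_id"),
        patient_id=get("patient_id"),
        hospital_id=get("hospital_id"),
        admission_date=date.fromisoformat(get("admission_date")),
        discharge_date=date.fromisoformat(get("discharge_date")),
        age=int(get("age")),
        diagnosis_codes=diagnosis,
        procedure_codes=procedures,
        drg_code=get("drg_code"),
        cost=float(get("cost")),
        ownership=get("ownership"),
    )


def read_hdc(
    path: str | Path,
    schema: str | Path | Mapping[str, str] | None = None,
) -> list[HDCRecord]:
    """Read an HDC table from a delimited text file.

    Raises :class:`SchemaError` when a mapped column is missing and
    :class:`RowValidationError` (listing 1-based data-row numbers) when any
    row fails to parse or violates a record invariant.
    """
    mapping = load_schema(schema)
    records: list[HDCRecord] = []
    errors: list[tuple[int, str]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return []
        missing = set(mapping.values()) - set(reader.fieldnames)
        if missing:
            raise SchemaError(f"missing mandatory column(s): {sorted(missing)}")
        for i, row in enumerate(reader, start=1):
            try:
                records.append(_parse_row(row, mapping))
            except (ValueError, KeyError) as exc:
                errors.append((i, str(exc)))
    if errors:
        raise RowValidationError(errors)
    return records


def write_hdc(
    records: Iterable[HDCRecord],
    path: str | Path,
    schema: str | Path | Mapping[str, str] | None = None,
) -> None:
    """Write records as CSV; inverse of :func:`read_hdc` for valid data."""
    mapping = load_schema(schema)
    fields = list(DEFAULT_SCHEMA)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([mapping[f] for f in fields])
        for r in records:
            writer.writerow(
                [
                    r.event_id,
                    r.patient_id,
                    r.hospital_id,
                    r.admission_date.isoformat(),
                    r.discharge_date.isoformat(),
                    r.age,
                    LIST_SEP.join(r.diagnosis_codes),
                    LIST_SEP.join(r.procedure_codes),
                    r.drg_code,
                    repr(r.cost),
                    r.ownership,
                ]
            )


def records_to_frame(records: Sequence[HDCRecord]) -> pd.DataFrame:
    """Tabular view of records (one row per event) with a ``los`` column."""
    return pd.DataFrame(
        {
            "event_id": [r.event_id for r in records],
            "patient_id": [r.patient_id for r in records],
            "hospital_id": [r.hospital_id for r in records],
            "admission_date": [r.admission_date for r in records],
            "discharge_date": [r.discharge_date for r in records],
            "age": [r.age for r in records],
            "drg_code": [r.drg_code for r in records],
            "cost": [r.cost for r in records],
            "ownership": [r.ownership for r in records],
            "los": [r.los for r in records],
        }
    )


def extract_cohort(records: Sequence[HDCRecord], config: CohortConfig) -> Cohort:
    """Select qualifying patients and keep all their in-window events.

    A patient qualifies when at least one of their events inside
    ``[window_start, window_end]`` (admission date, inclusive) carries a
    diagnosis code matching a ``disease_codes`` prefix in any position.
    """
    if not config.disease_codes:  # unreachable through CohortConfig; defensive
        raise ValueError("disease_codes must be non-empty")

    def in_window(r: HDCRecord) -> bool:
        return config.window_start <= r.admission_date <= config.window_end

    qualifying = {
        r.patient_id
        for r in records
        if in_window(r) and config.matches_disease(r.diagnosis_codes)
    }
    kept = tuple(r for r in records if r.patient_id in qualifying and in_window(r))
    return Cohort(records=kept, qualifying_patient_ids=frozenset(qualifying), config=config)


def save_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Serialize a cohort as ``records.csv`` plus a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_hdc(cohort.records, out / "records.csv")
    sidecar = {
        "qualifying_patient_ids": sorted(cohort.qualifying_patient_ids),
        "config": json.loads(cohort.config.model_dump_json()),
    }
    (out / "cohort.json").write_text(json.dumps(sidecar, indent=2))


def load_cohort(in_dir: str | Path) -> Cohort:
    src = Path(in_dir)
    sidecar = json.loads((src / "cohort.json").read_text())
    config = CohortConfig.model_validate(sidecar["config"])
    records = tuple(read_hdc(src / "records.csv"))
    return Cohort(
        records=records,
        qualifying_patient_ids=frozenset(sidecar["qualifying_patient_ids"]),
        config=config,
    )
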