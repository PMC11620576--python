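"""On-disk representation of billing cohorts.

A cohort is two CSV files:

* ``records.csv`` with header ``patient_id,record_class,code,count`` — one
  row per (patient, code), where ``count`` is the number of times the claim
  code appeared over the whole observation window.  Diagnosis codes are
  presence-only and are clamped to count 1 at read time.
* ``patients.csv`` with header ``patient_id,age_years,label_igan`` — one row
  per patient with the age at the point of the oldest data and the
  gold-standard IgA-nephropathy label (0/1).

No dates are represented: the analysis aggregates over the entire
observation window, so the schema stores whole-window counts only.
A JSON-lines dialect is accepted behind ``dialect="jsonl"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "RECORD_CLASSES",
    "BillingRecord",
    "Patient",
    "Cohort",
    "CohortError",
    "read_cohort",
    "write_cohort",
]

RECORD_CLASSES = ("diagnosis_icd10", "drug_mhlw", "procedure_billing")


class CohortError(ValueError):
    """Malformed or referentially inconsistent cohort data."""


@dataclass(frozen=True)
class BillingRecord:
    """One claim line: a code billed for a patient, with its whole-window count."""

    patient_id: str
    record_class: str  # one of RECORD_CLASSES
    code: str
    count: int

    def __post_init__(self) -> None:
        if self.record_class not in RECORD_CLASSES:
            raise CohortError(f"unknown record class {self.record_class!r}")
        if not self.code:
            raise CohortError("empty code")
        if self.record_class == "diagnosis_icd10":
            if self.count != 1:
                raise CohortError(
                    f"diagnosis records are presence-only (count 1), got {self.count}"
                )
        elif self.count < 1:
            raise CohortError(f"count must be >= 1, got {self.count}")


@dataclass(frozen=True)
class Patient:
    patient_id: str
    age_years: float
    label_igan: bool

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise CohortError("empty patient_id")
        if not (self.age_years == self.age_years and self.age_years >= 0):
            raise CohortError(f"age must be finite and >= 0, got {self.age_years}")


@dataclass
class Cohort:
    """A labeled claims cohort: patients plus their billing records."""

    patients: list[Patient]
    records: list[BillingRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortError(f"duplicate patient ids: {dupes[:5]}")
        known = set(ids)
        for r in self.records:
            if r.patient_id not in known:
                raise CohortError(
                    f"record references unknown patient {r.patient_id!r}"
                )

    def __len__(self) -> int:
        return len(self.patients)

    @property
    def n_igan(self) -> int:
        return sum(p.label_igan for p in self.patients)

    @property
    def prevalence(self) -> float:
        return self.n_igan / len(self.patients)

    def records_by_patient(self) -> dict[str, list[BillingRecord]]:
        out: dict[str, list[BillingRecord]] = {p.patient_id: [] for p in self.patients}
        for r in self.records:
            out[r.patient_id].append(r)
        return out

    def records_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.patient_id, r.record_class, r.code, r.count) for r in self.records],
            columns=["patient_id", "record_class", "code", "count"],
        )

    def patients_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.patient_id, p.age_years, int(p.label_igan)) for p in self.patients],
            columns=["patient_id", "age_years", "label_igan"],
        )


def _merge_records(rows: list[BillingRecord]) -> list[BillingRecord]:
    """Sum counts of duplicate (patient, class, code) rows; clamp diagnoses to 1.

    First-appearance order is preserved.
    """
    merged: dict[tuple[str, str, str], int] = {}
    order: list[tuple[str, str, str]] = []
    for r in rows:
        key = (r.patient_id, r.record_class, r.code)
        if key not in merged:
            order.append(key)
            merged[key] = 0
        merged[key] += r.count
    out = []
    for pid, cls, code in order:
        count = merged[(pid, cls, code)]
        if cls == "diagnosis_icd10":
            count = 1
        out.append(BillingRecord(pid, cls, code, count))
    return out


def _parse_record_row(row: dict, lineno: int, path) -> BillingRecord:
    try:
        count = int(row["count"])
        cls = str(row["record_class"])
        if cls == "diagnosis_icd10" and count >= 1:
            count = 1  # diagnoses are presence-only
        return BillingRecord(str(row["patient_id"]), cls, str(row["code"]), count)
    except (KeyError, ValueError, TypeError, CohortError) as exc:
        raise CohortError(f"{path}: line {lineno}: {exc}") from exc


def _parse_patient_row(row: dict, lineno: int, path) -> Patient:
    try:
        label = int(row["label_igan"])
        if label not in (0, 1):
            raise CohortError(f"label_igan must be 0 or 1, got {label}")
        return Patient(str(row["patient_id"]), float(row["age_years"]), bool(label))
    except (KeyError, ValueError, TypeError, CohortError) as exc:
        raise CohortError(f"{path}: line {lineno}: {exc}") from exc


def _read_table(path: Path, columns: tuple[str, ...], dialect: str) -> list[dict]:
    if dialect == "jsonl":
        rows = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    rows.append((json.loads(line), lineno))
                except json.JSONDecodeError as exc:
                    raise CohortError(f"{path}: line {lineno}: invalid JSON ({exc})")
        return rows
    if dialect != "csv":
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise CohortError(f"{path}: {exc}") from exc
    missing = set(columns) - set(frame.columns)
    if missing:
        raise CohortError(f"{path}: missing columns {sorted(missing)}")
    # +2: header line plus 1-based indexing
    return [(row, i + 2) for i, row in enumerate(frame.to_dict(orient="records"))]


def read_cohort(records_path, patients_path, dialect: str = "csv") -> Cohort:
    """Read and validate a cohort from its records and patients files.

    Duplicate (patient, class, code) rows have their counts summed
    (diagnoses stay clamped at 1).  A record referencing a patient absent
    from the patients file raises :class:`CohortError`.
    """
    records_path, patients_path = Path(records_path), Path(patients_path)
    patients = [
        _parse_patient_row(row, lineno, patients_path)
        for row, lineno in _read_table(patients_path, ("patient_id", "age_years", "label_igan"), dialect)
    ]
    raw = [
        _parse_record_row(row, lineno, records_path)
        for row, lineno in _read_table(records_path, ("patient_id", "record_class", "code", "count"), dialect)
    ]
    return Cohort(patients=patients, records=_merge_records(raw))


def write_cohort(cohort: Cohort, records_path, patients_path, dialect: str = "csv") -> None:
    """Write a cohort to disk in deterministic order.

    Records are merged and sorted by (patient_id, record_class, code);
    patients keep their cohort order.  Output is UTF-8 with LF endings.
    """
    records = sorted(
        _merge_records(cohort.records),
        key=lambda r: (r.patient_id, r.record_class, r.code),
    )
    if dialect == "jsonl":
        with open(records_path, "w", encoding="utf-8", newline="\n") as fh:
            for r in records:
                fh.write(json.dumps({
                    "patient_id": r.patient_id, "record_class": r.record_class,
                    "code": r.code, "count": r.count,
                }) + "\n")
        with open(patients_path, "w", encoding="utf-8", newline="\n") as fh:
            for p in cohort.patients:
                fh.write(json.dumps({
                    "patient_id": p.patient_id, "age_years": p.age_years,
                    "label_igan": int(p.label_igan),
                }) + "\n")
        return
    if dialect != "csv":
        raise ValueError(f"unknown dialect {dialect!r}")
    rec_frame = pd.DataFrame(
        [(r.patient_id, r.record_class, r.code, r.count) for r in records],
        columns=["patient_id", "record_class", "code", "count"],
    )
    rec_frame.to_csv(records_path, index=False, lineterminator="\n")
    cohort.patients_frame().to_csv(patients_path, index=False, lineterminator="\n")
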