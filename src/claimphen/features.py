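"""Patient x feature matrices under the three preprocessing patterns.

Pattern ``a`` (raw)
    One feature per distinct raw code; nothing is compiled.
Pattern ``b`` (compiled, nephrology excluded)
    Drug codes collapse to therapeutic class + administration route
    (``drug:2171:oral``); diagnosis codes collapse to their first two
    characters (``dx:J3``) except nephrology codes (ICD-10 N0xx-N2xx),
    which are dropped.
Pattern ``c`` (compiled, nephrology kept at three characters)
    As ``b``, but nephrology diagnoses are kept, compiled to their first
    three characters (``dx:N02``).

Procedure/billing item codes (D015, D412, N002, J098, ...) are never
compiled.  Count features sum within a group; diagnosis features are
clamped to 0/1.  An ``age_years`` column is always appended, and features
whose source code matches a denylist pattern (configurable "leaky"
variables) are dropped.  Feature order is sorted, so construction is
byte-for-byte deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .claims_io import Cohort
from .code_systems import (
    NEPHROLOGY_EXCLUDED,
    drug_group_key,
    icd10_group_key,
    matches_code_pattern,
)

__all__ = ["FeatureMatrix", "build_feature_matrix", "feature_count"]

PATTERNS = ("a", "b", "c")


@dataclass
class FeatureMatrix:
    """A dense patient x feature matrix with aligned labels."""

    patient_ids: list[str]
    feature_names: list[str]
    values: np.ndarray          # (n_patients, n_features), float64, >= 0
    labels: np.ndarray          # (n_patients,), bool
    pattern: str

    def __post_init__(self) -> None:
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature names")
        if self.values.shape != (len(self.patient_ids), len(self.feature_names)):
            raise ValueError("values shape does not match ids/names")
        if not np.isfinite(self.values).all() or (self.values < 0).any():
            raise ValueError("feature values must be finite and non-negative")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def subset(self, row_mask) -> "FeatureMatrix":
        row_mask = np.asarray(row_mask)
        idx = np.flatnonzero(row_mask) if row_mask.dtype == bool else row_mask
        return FeatureMatrix(
            patient_ids=[self.patient_ids[i] for i in idx],
            feature_names=self.feature_names,
            values=self.values[idx],
            labels=self.labels[idx],
            pattern=self.pattern,
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, index=self.patient_ids, columns=self.feature_names)
        frame.index.name = "patient_id"
        return frame

    def write_tsv(self, features_path, labels_path) -> None:
        self.to_frame().to_csv(features_path, sep="\t", lineterminator="\n")
        pd.DataFrame(
            {"patient_id": self.patient_ids, "label_igan": self.labels.astype(int)}
        ).to_csv(labels_path, sep="\t", index=False, lineterminator="\n")


def _feature_key(record_class: str, code: str, pattern: str) -> tuple[str, bool] | None:
    """Map a record to (feature name, is_binary), or None if excluded."""
    if record_class == "procedure_billing":
        return f"proc:{code}", False
    if record_class == "drug_mhlw":
        if pattern == "a":
            return f"drug:{code}", False
        return f"drug:{drug_group_key(code).key}", False
    # diagnosis
    if pattern == "a":
        return f"dx:{code}", True
    key = icd10_group_key(code, "pattern_b" if pattern == "b" else "pattern_c")
    if key is NEPHROLOGY_EXCLUDED:
        return None
    return f"dx:{key.key}", True


def build_feature_matrix(cohort: Cohort, pattern: str, denylist=()) -> FeatureMatrix:
    """Convert a cohort into a feature matrix under one preprocessing pattern.

    ``denylist`` is a list of wildcard code patterns; any feature whose
    source code matches one is dropped (the hook for removing variables
    that leak the label through local billing practice).
    """
    if pattern not in PATTERNS:
        raise ValueError(f"unknown preprocessing pattern {pattern!r}")
    if len(cohort.patients) == 0:
        raise ValueError("cannot build features for an empty cohort")

    denylist = tuple(denylist)
    row_of = {p.patient_id: i for i, p in enumerate(cohort.patients)}
    cells: dict[str, dict[int, float]] = {}
    binary: dict[str, bool] = {}
    for r in cohort.records:
        if any(matches_code_pattern(pat, r.code) for pat in denylist):
            continue
        mapped = _feature_key(r.record_class, r.code, pattern)
        if mapped is None:
            continue
        name, is_binary = mapped
        binary[name] = is_binary
        col = cells.setdefault(name, {})
        i = row_of[r.patient_id]
        col[i] = col.get(i, 0.0) + float(r.count)

    names = sorted(cells) + ["age_years"]
    values = np.zeros((len(cohort.patients), len(names)))
    for j, name in enumerate(names[:-1]):
        for i, v in cells[name].items():
            values[i, j] = min(v, 1.0) if binary[name] else v
    values[:, -1] = [p.age_years for p in cohort.patients]
    labels = np.array([p.label_igan for p in cohort.patients], dtype=bool)
    return FeatureMatrix(
        patient_ids=[p.patient_id for p in cohort.patients],
        feature_names=names,
        values=values,
        labels=labels,
        pattern=pattern,
    )


def feature_count(matrix: FeatureMatrix) -> int:
    """Number of feature columns (the published pattern-b count was 1,836
    on the original single-center cohort; it is cohort-dependent)."""
    return len(matrix.feature_names)
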