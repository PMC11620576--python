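"""Rule-based computable-phenotype criteria for IgA nephropathy.

The manual arm of the analysis defines criteria over billing codes —
presence of a diagnosis code, a procedure billed at least *t* times, or
any drug from a therapeutic class — combines them with AND/OR, and scores
each against the gold-standard label with the full set of 2x2
diagnostic-performance metrics (sensitivity, specificity, PV+, PV-,
accuracy).  A six-item score counts, per patient, how many
guideline-anchored factors (repeat serum-IgA measurement, biopsy with
immunostaining, RAS inhibitors, the dilazep drug class, corticosteroids,
tonsillitis treatment) are satisfied; the score feeds the ROC analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .claims_io import BillingRecord, Cohort
from .code_systems import Route, matches_code_pattern, parse_mhlw_code

__all__ = [
    "Criterion",
    "CriterionExpr",
    "AND",
    "OR",
    "ConfusionMetrics",
    "default_criteria",
    "default_score_factors",
    "table2_rows",
    "evaluate_criterion",
    "evaluate_expr",
    "confusion_metrics",
    "manual_score",
    "chi_square_2x2",
    "round_half_up",
    "metrics_report",
]

CRITERION_KINDS = ("diagnosis_present", "procedure_count_at_least", "drug_class_present")


@dataclass(frozen=True)
class Criterion:
    """An atomic billing-data criterion.

    ``code_patterns`` use the wildcard grammar of
    :func:`claimphen.code_systems.matches_code_pattern`.  For
    ``drug_class_present``, ``route`` optionally restricts matches to one
    administration route (derived from the MHLW compound-number range).
    """

    name: str
    kind: str
    code_patterns: tuple[str, ...]
    threshold: int = 1
    route: Route | None = None

    def __post_init__(self) -> None:
        if self.kind not in CRITERION_KINDS:
            raise ValueError(f"unknown criterion kind {self.kind!r}")
        if not self.code_patterns:
            raise ValueError(f"criterion {self.name!r} has no code patterns")
        if self.threshold < 1:
            raise ValueError(f"criterion {self.name!r}: threshold must be >= 1")

    def _matches(self, record: BillingRecord) -> bool:
        wanted = {
            "diagnosis_present": "diagnosis_icd10",
            "procedure_count_at_least": "procedure_billing",
            "drug_class_present": "drug_mhlw",
        }[self.kind]
        if record.record_class != wanted:
            return False
        if not any(matches_code_pattern(p, record.code) for p in self.code_patterns):
            return False
        if self.kind == "drug_class_present" and self.route is not None:
            return parse_mhlw_code(record.code).route == self.route
        return True

    def satisfied(self, records: list[BillingRecord]) -> bool:
        if self.kind == "procedure_count_at_least":
            total = sum(r.count for r in records if self._matches(r))
            return total >= self.threshold
        return any(self._matches(r) for r in records)


@dataclass(frozen=True)
class CriterionExpr:
    """A finite AND/OR tree over criteria."""

    op: str | None = None  # None for a leaf; "AND" / "OR" otherwise
    leaf: Criterion | None = None
    children: tuple["CriterionExpr", ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.op is None:
            if self.leaf is None:
                raise ValueError("leaf expression requires a criterion")
        else:
            if self.op not in ("AND", "OR"):
                raise ValueError(f"unknown operator {self.op!r}")
            if len(self.children) < 2:
                raise ValueError(f"{self.op} requires at least two children")

    def satisfied(self, records: list[BillingRecord]) -> bool:
        if self.op is None:
            return self.leaf.satisfied(records)
        results = (c.satisfied(records) for c in self.children)
        return all(results) if self.op == "AND" else any(results)


def leaf(criterion: Criterion) -> CriterionExpr:
    return CriterionExpr(leaf=criterion)


def AND(*children: CriterionExpr | Criterion) -> CriterionExpr:
    return CriterionExpr(op="AND", children=tuple(_as_expr(c) for c in children))


def OR(*children: CriterionExpr | Criterion) -> CriterionExpr:
    return CriterionExpr(op="OR", children=tuple(_as_expr(c) for c in children))


def _as_expr(c: CriterionExpr | Criterion) -> CriterionExpr:
    return c if isinstance(c, CriterionExpr) else leaf(c)


def default_criteria() -> dict[str, Criterion]:
    """The billing-code criterion definitions used throughout the analysis.

    Diagnosis criteria are ICD-10 families (N028 for IgA nephropathy, N00x
    through N08x for any glomerular disease, ...); procedure criteria are
    billing item codes (D015 serum IgA measurement at one or two
    thresholds, D412 percutaneous needle biopsy, N002 immunostaining,
    J098 tonsillitis treatment); drug criteria are MHLW therapeutic
    classes (2144/2149 renin-angiotensin system inhibitors, 2456
    corticosteroids — by route or any route — and 2171, the coronary
    vasodilator class containing dilazep).
    """
    c = {
        "igan_code": Criterion("igan_code", "diagnosis_present", ("N028",)),
        "any_glomerular": Criterion(
            "any_glomerular", "diagnosis_present",
            tuple(f"N0{i}x" for i in range(9)),
        ),
        "recurrent_hematuria": Criterion("recurrent_hematuria", "diagnosis_present", ("N02x",)),
        "chronic_gn": Criterion("chronic_gn", "diagnosis_present", ("N03x",)),
        "mesangial_gn": Criterion("mesangial_gn", "diagnosis_present", ("N033", "N043", "N053")),
        "serum_iga_once": Criterion("serum_iga_once", "procedure_count_at_least", ("D015",), threshold=1),
        "serum_iga_twice": Criterion("serum_iga_twice", "procedure_count_at_least", ("D015",), threshold=2),
        "needle_biopsy": Criterion("needle_biopsy", "procedure_count_at_least", ("D412",)),
        "immunostaining": Criterion("immunostaining", "procedure_count_at_least", ("N002",)),
        "tonsillitis_treatment": Criterion("tonsillitis_treatment", "procedure_count_at_least", ("J098",)),
        "ras_inhibitor": Criterion("ras_inhibitor", "drug_class_present", ("2144", "2149")),
        "corticosteroid_injectable": Criterion(
            "corticosteroid_injectable", "drug_class_present", ("2456",), route=Route.INFUSION,
        ),
        "corticosteroid_any": Criterion("corticosteroid_any", "drug_class_present", ("2456",)),
        "dilazep_class": Criterion("dilazep_class", "drug_class_present", ("2171",)),
    }
    return c


def table2_rows(criteria: dict[str, Criterion] | None = None) -> dict[str, CriterionExpr]:
    """The single and combined criteria of the manual performance analysis.

    Row keys follow the numbering/lettering of the published table:
    diagnostic components 1-6, treatment components a-e, and the combined
    rows prefixed by their anchor criterion.
    """
    c = criteria if criteria is not None else default_criteria()
    hema_or_gn = OR(c["recurrent_hematuria"], c["chronic_gn"])
    biopsy_stain = AND(c["needle_biopsy"], c["immunostaining"])
    rows: dict[str, CriterionExpr] = {
        "1_igan_code": leaf(c["igan_code"]),
        "2_hematuria_or_chronic_gn": hema_or_gn,
        "3_any_glomerular": leaf(c["any_glomerular"]),
        "4_serum_iga_once": leaf(c["serum_iga_once"]),
        "5_serum_iga_twice": leaf(c["serum_iga_twice"]),
        "6_biopsy_with_immunostaining": biopsy_stain,
        "a_dilazep_class": leaf(c["dilazep_class"]),
        "b_ras_inhibitor": leaf(c["ras_inhibitor"]),
        "c_corticosteroid_injectable": leaf(c["corticosteroid_injectable"]),
        "d_corticosteroid_any": leaf(c["corticosteroid_any"]),
        "e_tonsillitis": leaf(c["tonsillitis_treatment"]),
        # combined: codes of hematuria/chronic GN plus a condition
        "2+5_iga_twice": AND(hema_or_gn, c["serum_iga_twice"]),
        "2+5+c_steroid_inj": AND(hema_or_gn, c["serum_iga_twice"], c["corticosteroid_injectable"]),
        "2+6_biopsy_stain": AND(hema_or_gn, biopsy_stain),
        "2+6+c_steroid_inj": AND(hema_or_gn, biopsy_stain, c["corticosteroid_injectable"]),
        "2+a_dilazep": AND(hema_or_gn, c["dilazep_class"]),
        "2+b_ras": AND(hema_or_gn, c["ras_inhibitor"]),
        "2+c_steroid_inj": AND(hema_or_gn, c["corticosteroid_injectable"]),
        "2+e_tonsillitis": AND(hema_or_gn, c["tonsillitis_treatment"]),
        # combined: two or more serum-IgA measurements plus a condition
        "5+6_biopsy_stain": AND(c["serum_iga_twice"], biopsy_stain),
        "5+6+d_steroid_any": AND(c["serum_iga_twice"], biopsy_stain, c["corticosteroid_any"]),
        "5+a_dilazep": AND(c["serum_iga_twice"], c["dilazep_class"]),
        "5+b_ras": AND(c["serum_iga_twice"], c["ras_inhibitor"]),
        "5+c_steroid_inj": AND(c["serum_iga_twice"], c["corticosteroid_injectable"]),
    }
    return rows


def default_score_factors(criteria: dict[str, Criterion] | None = None) -> list[CriterionExpr]:
    """The six guideline-anchored factors of the manual score."""
    c = criteria if criteria is not None else default_criteria()
    return [
        leaf(c["serum_iga_twice"]),
        AND(c["needle_biopsy"], c["immunostaining"]),
        leaf(c["ras_inhibitor"]),
        leaf(c["dilazep_class"]),
        leaf(c["corticosteroid_any"]),
        leaf(c["tonsillitis_treatment"]),
    ]


def evaluate_criterion(criterion: Criterion, cohort: Cohort) -> np.ndarray:
    return evaluate_expr(leaf(criterion), cohort)


def evaluate_expr(expr: CriterionExpr, cohort: Cohort) -> np.ndarray:
    """Evaluate an expression per patient; boolean vector in cohort order."""
    by_patient = cohort.records_by_patient()
    return np.array(
        [expr.satisfied(by_patient[p.patient_id]) for p in cohort.patients],
        dtype=bool,
    )


@dataclass(frozen=True)
class ConfusionMetrics:
    """A 2x2 table against the gold standard, with the five derived metrics.

    ``ppv`` is NaN when there are no predicted positives (and ``npv`` when
    there are no predicted negatives) rather than 0, so degenerate rules
    are flagged instead of silently distorting sweeps.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else math.nan

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn) if (self.tn + self.fn) else math.nan

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.fp + self.fn + self.tn)

    def rounded(self, digits: int = 4) -> dict[str, float]:
        """Display rounding: half-up to ``digits`` decimal places."""
        return {
            "Sn": round_half_up(self.sensitivity, digits),
            "Sp": round_half_up(self.specificity, digits),
            "PPV": round_half_up(self.ppv, digits),
            "NPV": round_half_up(self.npv, digits),
            "Ac": round_half_up(self.accuracy, digits),
        }


def round_half_up(x: float, digits: int = 4) -> float:
    if math.isnan(x):
        return x
    scale = 10 ** digits
    return math.floor(x * scale + 0.5) / scale


def confusion_metrics(predicted, labels) -> ConfusionMetrics:
    """Cross a boolean prediction vector against the gold-standard labels."""
    predicted = np.asarray(predicted, dtype=bool)
    labels = np.asarray(labels, dtype=bool)
    if predicted.shape != labels.shape:
        raise ValueError(
            f"length mismatch: {predicted.shape} predictions vs {labels.shape} labels"
        )
    if labels.all() or not labels.any():
        raise ValueError("labels must contain at least one positive and one negative")
    tp = int(np.sum(predicted & labels))
    fp = int(np.sum(predicted & ~labels))
    fn = int(np.sum(~predicted & labels))
    tn = int(np.sum(~predicted & ~labels))
    return ConfusionMetrics(tp=tp, fp=fp, fn=fn, tn=tn)


def manual_score(cohort: Cohort, factors: list[CriterionExpr] | None = None) -> np.ndarray:
    """Per-patient count of satisfied scoring factors (0..len(factors))."""
    if factors is None:
        factors = default_score_factors()
    if not factors:
        raise ValueError("empty factor list")
    by_patient = cohort.records_by_patient()
    return np.array(
        [
            sum(f.satisfied(by_patient[p.patient_id]) for f in factors)
            for p in cohort.patients
        ],
        dtype=int,
    )


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction, 1 d.f.) for a 2x2 table
    [[a, b], [c, d]], with its upper-tail p-value."""
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("cell counts must be non-negative")
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("all margins of the 2x2 table must be positive")
    stat = n * (a * d - b * c) ** 2 / math.prod(margins)
    return stat, float(stats.chi2.sf(stat, df=1))


def metrics_report(cohort: Cohort, rows: dict[str, CriterionExpr] | None = None) -> "pd.DataFrame":
    """Evaluate a set of expressions and tabulate all metrics per row.

    Returns a DataFrame with columns Sn, Sp, PPV, NPV, Ac (4 d.p., half-up)
    and the raw TP/FP/FN/TN counts, indexed by row name.
    """
    import pandas as pd

    if rows is None:
        rows = table2_rows()
    labels = np.array([p.label_igan for p in cohort.patients], dtype=bool)
    out = []
    for name, expr in rows.items():
        m = confusion_metrics(evaluate_expr(expr, cohort), labels)
        rec = {"criterion": name, **m.rounded()}
        rec.update(TP=m.tp, FP=m.fp, FN=m.fn, TN=m.tn)
        out.append(rec)
    return pd.DataFrame(out).set_index("criterion")
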