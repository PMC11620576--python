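"""Criterion definitions, combined expressions, metrics, score, chi-square."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from claimphen.claims_io import BillingRecord, Cohort, Patient
from claimphen.criteria import (
    AND,
    OR,
    ConfusionMetrics,
    chi_square_2x2,
    confusion_metrics,
    default_criteria,
    default_score_factors,
    evaluate_criterion,
    evaluate_expr,
    leaf,
    manual_score,
    round_half_up,
)


def one_patient_cohort(records):
    recs = [BillingRecord("P1", *r) for r in records]
    return Cohort(patients=[Patient("P1", 50.0, True)], records=recs)


class TestDefaultCriteria:
    def test_igan_code_matches_n028(self):
        c = default_criteria()
        cohort = one_patient_cohort([("diagnosis_icd10", "N028", 1)])
        assert evaluate_criterion(c["igan_code"], cohort)[0]

    def test_serum_iga_threshold(self):
        c = default_criteria()
        once = one_patient_cohort([("procedure_billing", "D015", 1)])
        twice = one_patient_cohort([("procedure_billing", "D015", 2)])
        assert not evaluate_criterion(c["serum_iga_twice"], once)[0]
        assert evaluate_criterion(c["serum_iga_twice"], twice)[0]
        assert evaluate_criterion(c["serum_iga_once"], once)[0]

    def test_threshold_counts_only_matching_codes(self):
        c = default_criteria()
        cohort = one_patient_cohort(
            [("procedure_billing", "D015", 1), ("procedure_billing", "D016", 9)]
        )
        assert not evaluate_criterion(c["serum_iga_twice"], cohort)[0]

    def test_ras_inhibitor_covers_both_classes(self):
        c = default_criteria()
        for code in ("2149001F1021", "2144002F1021"):
            cohort = one_patient_cohort([("drug_mhlw", code, 1)])
            assert evaluate_criterion(c["ras_inhibitor"], cohort)[0]
        other = one_patient_cohort([("drug_mhlw", "2456001F1021", 1)])
        assert not evaluate_criterion(c["ras_inhibitor"], other)[0]

    def test_corticosteroid_route_restriction(self):
        c = default_criteria()
        oral = one_patient_cohort([("drug_mhlw", "2456001F1021", 1)])
        inj = one_patient_cohort([("drug_mhlw", "2456400A1021", 1)])
        assert not evaluate_criterion(c["corticosteroid_injectable"], oral)[0]
        assert evaluate_criterion(c["corticosteroid_injectable"], inj)[0]
        assert evaluate_criterion(c["corticosteroid_any"], oral)[0]
        assert evaluate_criterion(c["corticosteroid_any"], inj)[0]

    def test_any_glomerular_spans_n00_to_n08(self):
        c = default_criteria()
        assert evaluate_criterion(
            c["any_glomerular"], one_patient_cohort([("diagnosis_icd10", "N059", 1)])
        )[0]
        assert not evaluate_criterion(
            c["any_glomerular"], one_patient_cohort([("diagnosis_icd10", "N179", 1)])
        )[0]


class TestExpressions:
    def test_or_needs_one_member(self):
        c = default_criteria()
        expr = OR(c["recurrent_hematuria"], c["chronic_gn"])
        cohort = one_patient_cohort([("diagnosis_icd10", "N039", 1)])
        assert evaluate_expr(expr, cohort)[0]

    def test_and_needs_all_members(self):
        c = default_criteria()
        expr = AND(c["needle_biopsy"], c["immunostaining"])
        only_biopsy = one_patient_cohort([("procedure_billing", "D412", 1)])
        both = one_patient_cohort(
            [("procedure_billing", "D412", 1), ("procedure_billing", "N002", 1)]
        )
        assert not evaluate_expr(expr, only_biopsy)[0]
        assert evaluate_expr(expr, both)[0]

    def test_and_implies_or(self, generated_cohort):
        c = default_criteria()
        x, y = c["serum_iga_twice"], c["ras_inhibitor"]
        v_and = evaluate_expr(AND(x, y), generated_cohort)
        v_or = evaluate_expr(OR(x, y), generated_cohort)
        assert not (v_and & ~v_or).any()

    def test_or_sensitivity_and_and_specificity_dominate(self, table1_fixture):
        """Sn(OR) >= max Sn of members; Sp(AND) >= max Sp of members."""
        c = default_criteria()
        labels = np.array([p.label_igan for p in table1_fixture.patients])
        pairs = [(c["igan_code"], c["serum_iga_twice"]),
                 (c["dilazep_class"], c["ras_inhibitor"])]
        for x, y in pairs:
            mx = confusion_metrics(evaluate_criterion(x, table1_fixture), labels)
            my = confusion_metrics(evaluate_criterion(y, table1_fixture), labels)
            m_or = confusion_metrics(evaluate_expr(OR(x, y), table1_fixture), labels)
            m_and = confusion_metrics(evaluate_expr(AND(x, y), table1_fixture), labels)
            assert m_or.sensitivity >= max(mx.sensitivity, my.sensitivity)
            assert m_and.specificity >= max(mx.specificity, my.specificity)


class TestConfusionMetrics:
    def test_igan_code_row_of_published_table(self):
        """231 TP / 206 FN / 106 FP / 3200 TN reproduce the printed metrics."""
        m = ConfusionMetrics(tp=231, fn=206, fp=106, tn=3200)
        assert m.rounded() == {
            "Sn": 0.5286, "Sp": 0.9679, "PPV": 0.6855, "NPV": 0.9395, "Ac": 0.9166,
        }

    def test_degenerate_predictors(self):
        labels = np.array([True, True, False, False])
        all_pos = confusion_metrics(np.ones(4, bool), labels)
        assert all_pos.sensitivity == 1.0 and all_pos.specificity == 0.0
        assert math.isnan(all_pos.npv)
        perfect = confusion_metrics(labels, labels)
        for v in (perfect.sensitivity, perfect.specificity, perfect.ppv,
                  perfect.npv, perfect.accuracy):
            assert v == 1.0
        none_pos = confusion_metrics(np.zeros(4, bool), labels)
        assert math.isnan(none_pos.ppv)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_metrics([True], [True, False])

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([True, False], [True, True])

    @given(st.integers(1, 500), st.integers(1, 500), st.integers(1, 500), st.integers(1, 500))
    def test_metric_identities(self, tp, fp, fn, tn):
        """The five metric formulas and the accuracy decomposition hold exactly."""
        m = ConfusionMetrics(tp=tp, fp=fp, fn=fn, tn=tn)
        n = tp + fp + fn + tn
        prevalence = (tp + fn) / n
        assert m.sensitivity == tp / (tp + fn)
        assert m.specificity == tn / (tn + fp)
        assert m.ppv == tp / (tp + fp)
        assert m.npv == tn / (tn + fn)
        assert m.accuracy == (tp + tn) / n
        assert m.accuracy == pytest.approx(
            m.sensitivity * prevalence + m.specificity * (1 - prevalence)
        )

    def test_rounding_is_half_up(self):
        assert round_half_up(0.12345, 4) == 0.1235
        assert round_half_up(0.12344999, 4) == 0.1234


class TestManualScore:
    def test_no_records_scores_zero(self):
        cohort = one_patient_cohort([])
        assert manual_score(cohort)[0] == 0

    def test_hand_evaluated_example(self):
        """D015 x2 + biopsy + immunostain + oral steroid = 3 of 6 factors."""
        cohort = one_patient_cohort([
            ("procedure_billing", "D015", 2),
            ("procedure_billing", "D412", 1),
            ("procedure_billing", "N002", 1),
            ("drug_mhlw", "2456001F1021", 1),
        ])
        assert manual_score(cohort)[0] == 3

    def test_six_default_factors(self):
        assert len(default_score_factors()) == 6

    def test_monotone_in_records(self):
        base = [("procedure_billing", "D015", 2)]
        extras = [
            ("procedure_billing", "D412", 1),
            ("procedure_billing", "N002", 1),
            ("drug_mhlw", "2149001F1021", 1),
            ("drug_mhlw", "2171005F2021", 1),
            ("procedure_billing", "J098", 1),
        ]
        prev = -1
        for stop in range(len(extras) + 1):
            score = manual_score(one_patient_cohort(base + extras[:stop]))[0]
            assert score >= prev
            prev = score

    def test_empty_factor_list_errors(self):
        with pytest.raises(ValueError):
            manual_score(one_patient_cohort([]), factors=[])

    def test_score_bounded_by_factor_count(self, generated_cohort):
        scores = manual_score(generated_cohort)
        assert scores.min() >= 0 and scores.max() <= 6


class TestChiSquare:
    def test_proportional_table_is_zero(self):
        stat, p = chi_square_2x2(20, 40, 10, 20)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_symmetric_table_is_zero(self):
        assert chi_square_2x2(10, 10, 10, 10)[0] == pytest.approx(0.0)

    def test_against_brute_force_formula(self):
        """N(ad-bc)^2 / product-of-margins, on the N05x row's 2x2 table."""
        a, b, c, d = 31, 406, 203, 3103
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        stat, p = chi_square_2x2(a, b, c, d)
        assert stat == pytest.approx(expected, rel=1e-12)
        assert 0 < p < 1

    @given(st.integers(1, 50), st.integers(1, 50), st.integers(1, 50), st.integers(1, 50))
    def test_matches_scipy_uncorrected(self, a, b, c, d):
        from scipy.stats import chi2_contingency

        stat, p = chi_square_2x2(a, b, c, d)
        ref = chi2_contingency([[a, b], [c, d]], correction=False)
        assert stat == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError):
            chi_square_2x2(0, 0, 5, 5)
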