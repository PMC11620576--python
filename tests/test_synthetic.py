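"""Fixture exactness and generator distributional contracts."""

import numpy as np
import pytest

from claimphen.claims_io import CohortError
from claimphen.code_systems import parse_mhlw_code
from claimphen.criteria import default_criteria, evaluate_criterion
from claimphen.synthetic import (
    CohortSpec,
    build_table1_fixture,
    default_spec,
    estimate_marginals,
    generate_cohort,
    serum_iga_split,
    spec_marginals,
)


class TestDefaultSpec:
    def test_published_marginal_counts(self):
        spec = default_spec()
        assert spec.n_igan == 437 and spec.n_non == 3306
        assert spec.dx_freq["N028"] == (231, 106)
        assert spec.proc_freq["D412"] == (162, 385)
        assert spec.proc_freq["J098"] == (2, 0)
        assert spec.iga_split_igan == (85, 191)
        assert spec.iga_split_non == (1049, 562)
        assert spec.any_glomerular_total == (380, 1327)
        assert spec.cs_any == (144, 552) and spec.cs_injectable == (60, 151)

    def test_counts_exceeding_class_size_rejected(self):
        with pytest.raises(CohortError):
            CohortSpec(dx_freq={"N028": (500, 106)})
        with pytest.raises(CohortError):
            CohortSpec(cs_injectable=(200, 151))  # injectable > any


class TestFixture:
    def test_cohort_shape(self, table1_fixture):
        assert len(table1_fixture) == 3743
        assert table1_fixture.n_igan == 437

    def test_marginals_match_spec_exactly(self, table1_fixture):
        spec = default_spec()
        marg = estimate_marginals(table1_fixture)
        for code, (ki, kn) in spec.dx_freq.items():
            if ki + kn:
                row = marg.loc[("diagnosis_icd10", code)]
                assert (row["n_igan"], row["n_non"]) == (ki, kn), code
        for code, (ki, kn) in spec.proc_freq.items():
            if ki + kn:
                row = marg.loc[("procedure_billing", code)]
                assert (row["n_igan"], row["n_non"]) == (ki, kn), code
        assert serum_iga_split(table1_fixture) == ((85, 191), (1049, 562))

    def test_family_union_marginals(self, table1_fixture):
        """The published family-level counts (not just per-code ones) hold."""
        c = default_criteria()
        labels = np.array([p.label_igan for p in table1_fixture.patients])
        def counts(criterion):
            v = evaluate_criterion(c[criterion], table1_fixture)
            return int(v[labels].sum()), int(v[~labels].sum())
        assert counts("any_glomerular") == (380, 1327)
        assert counts("recurrent_hematuria") == (235, 158)
        assert counts("chronic_gn") == (275, 718)
        assert counts("igan_code") == (231, 106)
        assert counts("serum_iga_twice") == (191, 562)
        assert counts("corticosteroid_injectable") == (60, 151)
        assert counts("corticosteroid_any") == (144, 552)

    def test_deterministic(self):
        a, b = build_table1_fixture(), build_table1_fixture()
        assert a.patients == b.patients and a.records == b.records


class TestGenerator:
    def test_seed_reproducibility(self):
        a = generate_cohort(seed=42).cohort
        b = generate_cohort(seed=42).cohort
        assert a.patients == b.patients and a.records == b.records
        c = generate_cohort(seed=43).cohort
        assert c.records != a.records

    def test_prevalence_exact(self, generated_cohort):
        assert len(generated_cohort) == 3743
        assert generated_cohort.n_igan == 437

    def test_codes_well_formed(self, generated_cohort):
        import re

        icd = re.compile(r"^[A-Z][0-9A-Z]{2,3}$")
        proc = re.compile(r"^[A-Z][0-9]{3}$")
        for r in generated_cohort.records:
            if r.record_class == "drug_mhlw":
                parse_mhlw_code(r.code)  # raises if malformed
            elif r.record_class == "diagnosis_icd10":
                assert icd.match(r.code), r.code
            else:
                assert proc.match(r.code), r.code

    def test_marginals_near_spec(self, generated_cohort):
        """Single-replicate sanity: each signal marginal within 4 binomial SE."""
        spec = default_spec()
        marg = spec_marginals(generated_cohort, spec)
        expected = spec.freq_table()
        for key in expected.index:
            for col, n_class in (("n_igan", spec.n_igan), ("n_non", spec.n_non)):
                k = expected.loc[key, col]
                p = k / n_class
                se = np.sqrt(max(n_class * p * (1 - p), 1.0))
                assert abs(marg.loc[key, col] - k) <= 4 * se + 1, (key, col)

    def test_zero_dependence_uncouples_linked_codes(self):
        """dependence_strength 0: biopsy and immunostaining co-occur at chance."""
        spec = CohortSpec(dependence_strength=0.0, n_noise_codes=0)
        carriers = {"D412": set(), "N002": set()}
        cohort = generate_cohort(spec, seed=5).cohort
        for r in cohort.records:
            if r.code in carriers:
                carriers[r.code].add(r.patient_id)
        non_ids = {p.patient_id for p in cohort.patients if not p.label_igan}
        a = carriers["D412"] & non_ids
        b = carriers["N002"] & non_ids
        x = np.array([[len(a & b), len(a - b)], [len(b - a), len(non_ids - a - b)]])
        phi = (x[0, 0] * x[1, 1] - x[0, 1] * x[1, 0]) / np.sqrt(
            x[0].sum() * x[1].sum() * x[:, 0].sum() * x[:, 1].sum()
        )
        assert abs(phi) < 0.08

    def test_positive_dependence_couples_linked_codes(self, generated_cohort):
        carriers = {"D412": set(), "N002": set()}
        for r in generated_cohort.records:
            if r.code in carriers:
                carriers[r.code].add(r.patient_id)
        non_ids = {p.patient_id for p in generated_cohort.patients if not p.label_igan}
        a = carriers["D412"] & non_ids
        b = carriers["N002"] & non_ids
        x = np.array([[len(a & b), len(a - b)], [len(b - a), len(non_ids - a - b)]])
        phi = (x[0, 0] * x[1, 1] - x[0, 1] * x[1, 0]) / np.sqrt(
            x[0].sum() * x[1].sum() * x[:, 0].sum() * x[:, 1].sum()
        )
        assert phi > 0.1

    def test_age_moments_near_spec(self, generated_cohort):
        spec = default_spec()
        ages_igan = [p.age_years for p in generated_cohort.patients if p.label_igan]
        ages_non = [p.age_years for p in generated_cohort.patients if not p.label_igan]
        assert np.mean(ages_igan) == pytest.approx(spec.age_mean_igan, abs=3.0)
        # non-IgAN mean shifts slightly upward from truncation at zero
        assert np.mean(ages_non) == pytest.approx(spec.age_mean_non, abs=4.0)
        assert min(min(ages_igan), min(ages_non)) >= 0.0

    def test_estimate_marginals_matches_brute_force(self):
        spec = CohortSpec(
            n_igan=20, n_non=60,
            dx_freq={"N028": (10, 3), "N039": (12, 20)},
            proc_freq={"D412": (8, 10), "N002": (7, 9), "J098": (1, 0)},
            drug_freq={"2149001F1021": (12, 25), "2171005F2021": (10, 20)},
            iga_split_igan=(4, 9), iga_split_non=(30, 15),
            cs_any=(7, 10), cs_injectable=(3, 4),
            any_glomerular_total=(12, 20), n_noise_codes=10,
        )
        cohort = generate_cohort(spec, seed=9).cohort
        marg = estimate_marginals(cohort)
        label_of = {p.patient_id: p.label_igan for p in cohort.patients}
        for (cls, code), row in marg.iterrows():
            pats = {r.patient_id for r in cohort.records
                    if r.record_class == cls and r.code == code}
            assert row["n_igan"] == sum(label_of[p] for p in pats)
            assert row["n_non"] == sum(not label_of[p] for p in pats)

    def test_empty_cohort_marginals(self):
        from claimphen.claims_io import Cohort, Patient

        marg = estimate_marginals(Cohort(patients=[Patient("P1", 1.0, True)]))
        assert marg.empty
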