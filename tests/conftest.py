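import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from claimphen.claims_io import BillingRecord, Cohort, Patient
from claimphen.synthetic import build_table1_fixture, default_spec, generate_cohort


@pytest.fixture(scope="session")
def table1_fixture():
    """Deterministic cohort reproducing the published marginal counts."""
    return build_table1_fixture(default_spec())


@pytest.fixture(scope="session")
def generated_cohort():
    """One stochastic synthetic cohort at the default spec."""
    return generate_cohort(default_spec(), seed=1).cohort


@pytest.fixture
def toy_cohort():
    """Three hand-built patients exercising every record class."""
    patients = [
        Patient("P1", 40.0, True),
        Patient("P2", 55.0, False),
        Patient("P3", 63.0, False),
    ]
    records = [
        BillingRecord("P1", "diagnosis_icd10", "N028", 1),
        BillingRecord("P1", "diagnosis_icd10", "N039", 1),
        BillingRecord("P1", "procedure_billing", "D015", 3),
        BillingRecord("P1", "drug_mhlw", "2171005F2021", 2),
        BillingRecord("P1", "drug_mhlw", "2171010F1011", 1),
        BillingRecord("P2", "diagnosis_icd10", "J359", 1),
        BillingRecord("P2", "procedure_billing", "D412", 1),
        BillingRecord("P3", "drug_mhlw", "2456400A1021", 1),
    ]
    return Cohort(patients=patients, records=records)
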