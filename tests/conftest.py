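from datetime import datetime, timedelta

import pytest

import autopesi as ap
from autopesi.ehr_model import (
    OxygenSupportRecord,
    PatientSnapshot,
    ProblemEntry,
    VitalKind,
    VitalSample,
)

TRIGGER = datetime(2023, 1, 10, 12, 0, 0)


def make_snapshot(**overrides) -> PatientSnapshot:
    """A clean 45-year-old female encounter; override fields as needed."""
    base = dict(
        patient_id="T0001",
        age_years=45,
        sex_assigned_at_birth="female",
        administrative_sex="female",
        problem_list=[],
        medical_history=[],
        chief_complaints=["chest pain"],
        vitals=[],
        oxygen_records=[],
        gcs_records=[(TRIGGER - timedelta(minutes=60), 15)],
        home_o2_lpm=0.0,
        prior_encounter_count=3,
        trigger_time=TRIGGER,
    )
    base.update(overrides)
    return PatientSnapshot(**base)


def vital(kind: str, value: float, minutes_before: float = 60.0) -> VitalSample:
    return VitalSample(
        time=TRIGGER - timedelta(minutes=minutes_before), kind=VitalKind(kind), value=value
    )


def problem(code: str, status: str = "active", days_before: int = 100) -> ProblemEntry:
    return ProblemEntry(
        snomed_code=code, status=status, recorded_time=TRIGGER - timedelta(days=days_before)
    )


def oxygen(device: str, flow: float, minutes_before: float = 30.0) -> OxygenSupportRecord:
    return OxygenSupportRecord(
        time=TRIGGER - timedelta(minutes=minutes_before), device=device, flow_lpm=flow
    )


@pytest.fixture(scope="session")
def graph():
    return ap.default_concept_graph()


@pytest.fixture(scope="session")
def replica():
    return ap.build_study_replica()


@pytest.fixture(scope="session")
def toy_graph():
    """5-node is-a toy: skin_ca -> cancer_root -> disease; lung_ca -> cancer_root;
    skin_ca excluded from the cancer category."""
    return ap.ConceptGraph.from_edges(
        edges=[("cancer_root", "disease"), ("lung_ca", "cancer_root"), ("skin_ca", "cancer_root"),
               ("hf_root", "disease")],
        category_roots={"cancer": ["cancer_root"], "heart_failure": ["hf_root"],
                        "chronic_lung_disease": ["cld_root"]},
        exclusions={"cancer": ["skin_ca"]},
    )
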