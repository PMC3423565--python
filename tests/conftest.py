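"""Shared fixtures: record builders and the packaged survey cohort."""

from __future__ import annotations

import pytest

from alf_triage import (ComaGrade, Etiology, EtiologyCode, LabPanel,
                        Outcome, PatientRecord, Treatment, classify, survey)


def make_record(**overrides) -> PatientRecord:
    """A valid acute-type fulminant-hepatitis record; override any field.

    Lab fields may be overridden individually via pt_percent / inr /
    total_bilirubin / direct_bilirubin / platelets keywords.
    """
    lab_fields = {"pt_percent": 30.0, "inr": 1.8, "total_bilirubin": 12.0,
                  "direct_bilirubin": 7.2, "platelets": 8.0}
    for key in list(overrides):
        if key in lab_fields:
            lab_fields[key] = overrides.pop(key)
    defaults = dict(
        patient_id="P001",
        age_years=50,
        labs=LabPanel(**lab_fields),
        etiology=EtiologyCode(Etiology.I_VIRAL),
        onset_to_encephalopathy_days=7,
        onset_to_labs_weeks=1.0,
        liver_atrophy=False,
        coma_grade=ComaGrade.III,
        prior_liver_function_normal=True,
        habitual_alcohol_as_cause=False,
        treatment=Treatment.MEDICAL_ONLY,
        outcome=Outcome.SURVIVED,
    )
    defaults.update(overrides)
    rec = PatientRecord(**defaults)
    rec.validate()
    return rec


@pytest.fixture(scope="session")
def survey_records():
    return survey.expand_strata()


@pytest.fixture(scope="session")
def survey_diagnoses(survey_records):
    return [classify(r) for r in survey_records]
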