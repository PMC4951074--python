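import pytest

from carat.records import (
    BleedRiskFactors,
    PatientRecord,
    SafetyChecklist,
    StrokeRiskFactors,
)


def make_patient(**overrides) -> PatientRecord:
    """Build a valid patient, auto-syncing the derived consistency fields.

    ``stroke.age_ge_75`` follows the (possibly overridden) age and
    ``safety.polypharmacy_ge4`` follows the prescription count unless the
    caller supplies the sub-model explicitly with matching values.
    """
    data = dict(
        patient_id="p00001",
        gp_id="igp000",
        arm="intervention",
        age=70,
        sex="male",
        chronic_condition_count=6,
        rx_med_count=9,
        otc_med_count=1,
        afib_duration="ge_5y",
        afib_type="persistent",
        prior_hospitalization=False,
        hospitalization_reason=None,
        rhythm="controlled_af",
        stroke=None,
        bleed=BleedRiskFactors(),
        safety=None,
        baseline_therapy="warfarin",
        inr_subtherapeutic=None,
    )
    data.update(overrides)
    if data["stroke"] is None:
        data["stroke"] = StrokeRiskFactors(age_ge_75=data["age"] >= 75)
    elif "age" in overrides and "stroke" not in overrides:
        data["stroke"] = data["stroke"].model_copy(
            update={"age_ge_75": data["age"] >= 75}
        )
    if data["safety"] is None:
        data["safety"] = SafetyChecklist(polypharmacy_ge4=data["rx_med_count"] >= 4)
    return PatientRecord(**data)


@pytest.fixture
def patient_factory():
    return make_patient


@pytest.fixture
def small_cohort():
    """Deterministic 3-patient mini-cohort spanning the therapy classes."""
    return [
        make_patient(patient_id="p00001", baseline_therapy="warfarin"),
        make_patient(
            patient_id="p00002",
            gp_id="igp001",
            age=80,
            sex="female",
            baseline_therapy="aspirin_only",
            stroke=StrokeRiskFactors(age_ge_75=True, hypertension=True),
        ),
        make_patient(
            patient_id="p00003",
            gp_id="cgp000",
            arm="control",
            rx_med_count=2,
            baseline_therapy="none",
            prior_hospitalization=True,
            hospitalization_reason="stroke",
        ),
    ]
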