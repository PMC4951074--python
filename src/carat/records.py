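"""Domain types for the antithrombotic-therapy cohort.

One :class:`PatientRecord` holds everything the risk assessment tool needs
for a single enrolled patient: demographics, atrial-fibrillation history,
the stroke- and bleeding-risk factor sets, the medication-safety checklist,
the baseline antithrombotic regimen, and the trial bookkeeping fields
(general-practitioner cluster id and study arm).

Eligibility and internal-consistency rules are enforced at construction:
patients must be at least 65 years old, the "aged >= 75" stroke-risk flag
must agree with the recorded age, and the polypharmacy checklist flag must
agree with the prescription-medication count.
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator


class Arm(str, enum.Enum):
    intervention = "intervention"
    control = "control"


class Sex(str, enum.Enum):
    male = "male"
    female = "female"


class AfibDuration(str, enum.Enum):
    """Time since atrial fibrillation diagnosis, in the registry's bands."""

    lt_3mo = "lt_3mo"
    lt_12mo = "lt_12mo"
    lt_2y = "lt_2y"
    lt_5y = "lt_5y"
    ge_5y = "ge_5y"


class AfibType(str, enum.Enum):
    paroxysmal = "paroxysmal"
    persistent = "persistent"
    new_onset = "new_onset"
    unknown = "unknown"


class HospitalizationReason(str, enum.Enum):
    af_management = "af_management"
    stroke = "stroke"
    tia = "tia"
    other = "other"


class Rhythm(str, enum.Enum):
    sinus = "sinus"
    controlled_af = "controlled_af"
    uncontrolled_af = "uncontrolled_af"


class Regimen(str, enum.Enum):
    """Antithrombotic regimen at the granularity the trial analysed."""

    warfarin = "warfarin"
    warfarin_plus_antiplatelet = "warfarin_plus_antiplatelet"
    aspirin_only = "aspirin_only"
    clopidogrel_only = "clopidogrel_only"
    dabigatran = "dabigatran"
    dabigatran_plus_clopidogrel = "dabigatran_plus_clopidogrel"
    other = "other"
    none = "none"


class TherapyClass(str, enum.Enum):
    anticoagulant = "anticoagulant"
    antiplatelet = "antiplatelet"
    none = "none"
    other = "other"


#: Fixed, total mapping regimen -> effectiveness class. Warfarin- and
#: dabigatran-based regimens (with or without an antiplatelet on top) count
#: as anticoagulant therapy; aspirin or clopidogrel monotherapy as
#: antiplatelet therapy.
_THERAPY_CLASS: dict[Regimen, TherapyClass] = {
    Regimen.warfarin: TherapyClass.anticoagulant,
    Regimen.warfarin_plus_antiplatelet: TherapyClass.anticoagulant,
    Regimen.dabigatran: TherapyClass.anticoagulant,
    Regimen.dabigatran_plus_clopidogrel: TherapyClass.anticoagulant,
    Regimen.aspirin_only: TherapyClass.antiplatelet,
    Regimen.clopidogrel_only: TherapyClass.antiplatelet,
    Regimen.none: TherapyClass.none,
    Regimen.other: TherapyClass.other,
}


def therapy_class(regimen: Regimen | str) -> TherapyClass:
    """Map a regimen to its therapy class (total over the enum)."""
    return _THERAPY_CLASS[Regimen(regimen)]


def primary_agent(regimen: Regimen | str) -> str:
    """The principal agent of a regimen, ignoring add-on antiplatelets."""
    r = Regimen(regimen)
    if r in (Regimen.warfarin, Regimen.warfarin_plus_antiplatelet):
        return "warfarin"
    if r in (Regimen.dabigatran, Regimen.dabigatran_plus_clopidogrel):
        return "dabigatran"
    if r is Regimen.aspirin_only:
        return "aspirin"
    if r is Regimen.clopidogrel_only:
        return "clopidogrel"
    return r.value  # "none" / "other"


class StrokeRiskFactors(BaseModel):
    """The five CHADS2 components."""

    model_config = ConfigDict(extra="forbid")

    chf: bool = False
    hypertension: bool = False
    age_ge_75: bool = False
    diabetes: bool = False
    prior_stroke_or_tia: bool = False


class BleedRiskFactors(BaseModel):
    """HEMORR2HAGES components.

    ``age_gt_75`` and ``genetic_factor`` are the optional extensions of the
    full published score; they default to False and are excluded from the
    default score (see :mod:`carat.scoring`).
    """

    model_config = ConfigDict(extra="forbid")

    hepatic_or_renal: bool = False
    alcohol_abuse: bool = False
    malignancy: bool = False
    reduced_platelets: bool = False
    rebleed_risk: bool = False
    uncontrolled_htn: bool = False
    anemia: bool = False
    falls_risk: bool = False
    prior_hemorrhagic_stroke: bool = False
    age_gt_75: bool = False
    genetic_factor: bool = False


class SafetyChecklist(BaseModel):
    """Medication-safety and medication-management checklist."""

    model_config = ConfigDict(extra="forbid")

    allergy_warfarin_aspirin: bool = False
    adverse_reaction: bool = False
    interacting_medication: bool = False
    declined_therapy: bool = False
    contraindication: bool = False
    failed_therapy: bool = False
    educated: bool = False
    polypharmacy_ge4: bool = False
    noncompliant: bool = False
    needs_assistance: bool = False
    access_difficulty: bool = False
    residential_care: bool = False
    cognitive_impairment: bool = False
    vision_impairment: bool = False
    hearing_impairment: bool = False
    language_barrier: bool = False
    mobility_disorder: bool = False
    functional_impairment: bool = False


class PatientRecord(BaseModel):
    model_config = ConfigDict(extra="forbid")

    patient_id: str
    gp_id: str
    arm: Arm
    age: int = Field(ge=0)
    sex: Sex
    chronic_condition_count: int = Field(ge=0)
    rx_med_count: int = Field(ge=0)
    otc_med_count: int = Field(ge=0)
    afib_duration: AfibDuration
    afib_type: AfibType
    prior_hospitalization: bool
    hospitalization_reason: Optional[HospitalizationReason] = None
    rhythm: Rhythm
    stroke: StrokeRiskFactors
    bleed: BleedRiskFactors
    safety: SafetyChecklist
    baseline_therapy: Regimen
    # Optional: True when the patient is on warfarin with a sub-therapeutic
    # INR; drives the dose-adjust recommendation.
    inr_subtherapeutic: Optional[bool] = None

    @model_validator(mode="after")
    def _consistency(self) -> "PatientRecord":
        if self.age < 65:
            raise ValueError(
                f"patient {self.patient_id!r}: age {self.age} < 65 "
                "(cohort eligibility requires age >= 65)"
            )
        if self.stroke.age_ge_75 != (self.age >= 75):
            raise ValueError(
                f"patient {self.patient_id!r}: stroke.age_ge_75="
                f"{self.stroke.age_ge_75} inconsistent with age {self.age}"
            )
        if self.safety.polypharmacy_ge4 != (self.rx_med_count >= 4):
            raise ValueError(
                f"patient {self.patient_id!r}: safety.polypharmacy_ge4="
                f"{self.safety.polypharmacy_ge4} inconsistent with "
                f"rx_med_count {self.rx_med_count}"
            )
        return self

    @property
    def baseline_class(self) -> TherapyClass:
        return therapy_class(self.baseline_therapy)
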