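"""Score one patient and run the recommendation cascade.

Builds a typical high-stroke-risk, low-bleed-risk 78-year-old on
combination warfarin + aspirin and shows how the tool scores and advises.
"""

from carat import (
    BleedRiskFactors,
    PatientRecord,
    SafetyChecklist,
    StrokeRiskFactors,
    assess,
    recommend,
)

patient = PatientRecord(
    patient_id="example-001",
    gp_id="gp-07",
    arm="intervention",
    age=78,
    sex="female",
    chronic_condition_count=6,
    rx_med_count=9,
    otc_med_count=2,
    afib_duration="ge_5y",
    afib_type="persistent",
    prior_hospitalization=False,
    rhythm="controlled_af",
    stroke=StrokeRiskFactors(age_ge_75=True, hypertension=True, chf=True),
    bleed=BleedRiskFactors(),
    safety=SafetyChecklist(polypharmacy_ge4=True, needs_assistance=True),
    baseline_therapy="warfarin_plus_antiplatelet",
)

assessment = assess(patient)
print(f"CHADS2 score:        {assessment.chads2}  -> stroke risk {assessment.stroke_category.value}")
print(f"HEMORR2HAGES score:  {assessment.hemorrhages}  -> bleed risk {assessment.bleed_category.value}")

rec = recommend(patient, assessment)
print(f"Recommended therapy: {rec.therapy.value}")
print(f"Rationale code:      {rec.rationale[0]}")
print(f"Management flags:    {rec.flags}")
print(f"Change required:     {rec.change_required}")

# A CHADS2 of 3 (CHF + hypertension + age >= 75) puts her at high stroke
# risk; with a HEMORR2HAGES of 0 (low bleed risk) the cascade recommends
# warfarin monotherapy, which is a change from the baseline combination
# regimen (an add-on antiplatelet without a coded indication). The
# polypharmacy and assistance flags are attached for the prescriber but
# do not alter the risk-based recommendation.
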