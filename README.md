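# carat

Decision support and trial analytics for antithrombotic prescribing in
atrial fibrillation (AFib).

Elderly AFib patients face a trade-off between stroke prophylaxis and
bleeding risk. Computerized risk-assessment tools score both risks,
flag medication-safety issues, and recommend a therapy — warfarin,
aspirin, or none — for the general practitioner (GP) to weigh. `carat`
is a tested re-implementation of that workflow together with the
statistical layer of a cluster-randomized prescribing trial, plus a
synthetic-cohort simulator so every component is reproducible without
patient data.

## What it computes

**Risk scores.** CHADS₂ (stroke): CHF, hypertension, age ≥ 75 and
diabetes score 1 each, prior stroke/TIA scores 2 (range 0–6; banded
0 low / 1 intermediate / ≥2 high). HEMORR₂HAGES (bleeding): additive,
re-bleeding risk counts 2, every other component 1 (banded 0–1 / 2–3 /
≥4). Cutpoints are configurable.

**Recommendation cascade.** A declarative, ordered rule set maps
(stroke category × bleed category × safety checklist) to a therapy with
a rationale code; management-burden flags are attached without altering
the risk-based choice. Novel oral anticoagulants are never recommended.

**Change taxonomy and agreement.** Therapy transitions classify as
upgrade / side-step / downgrade on the effectiveness ordering
none < antiplatelet < anticoagulant (plus no-change and dose-adjust);
tool-vs-GP agreement is summarised as percent agreement (regimen and
class level) and the Fleiss κ statistic
κ = (P̄ − P̄ₑ)/(1 − P̄ₑ).

**Trial statistics.** Between-arm comparisons (Pearson χ², Fisher exact
when an expected cell < 5, Welch t, Mann–Whitney/Kruskal–Wallis),
univariate logistic screening at P < 0.10, forward stepwise (Wald)
logistic regression with odds ratios, cluster-robust 95% CIs,
Cox–Snell / Nagelkerke pseudo-R² and 0.5-cutoff classification rate.

**Simulation.** A cohort generator with GP-level clustering — a
beta-distributed prescribing propensity per GP yields an exact target
intracluster correlation (default 0.03) of baseline anticoagulant use —
plus a GP-decision simulator and a one-way ANOVA ICC estimator.

## Worked example

```python
from carat import (PatientRecord, StrokeRiskFactors, BleedRiskFactors,
                   SafetyChecklist, assess, recommend)

patient = PatientRecord(
    patient_id="example-001", gp_id="gp-07", arm="intervention",
    age=78, sex="female", chronic_condition_count=6, rx_med_count=9,
    otc_med_count=2, afib_duration="ge_5y", afib_type="persistent",
    prior_hospitalization=False, rhythm="controlled_af",
    stroke=StrokeRiskFactors(age_ge_75=True, hypertension=True, chf=True),
    bleed=BleedRiskFactors(),
    safety=SafetyChecklist(polypharmacy_ge4=True, needs_assistance=True),
    baseline_therapy="warfarin_plus_antiplatelet",
)
a = assess(patient)
r = recommend(patient, a)
```

Running `python examples/01_score_and_recommend.py` prints:

```
CHADS2 score:        3  -> stroke risk high
HEMORR2HAGES score:  0  -> bleed risk low
Recommended therapy: warfarin
Rationale code:      STROKE_RISK_DOMINANT
Management flags:    ['POLYPHARMACY_GE4', 'NEEDS_ASSISTANCE']
Change required:     True
```

CHF + hypertension + age ≥ 75 give CHADS₂ = 3 (high stroke risk); with
no bleeding risk factors the cascade recommends warfarin monotherapy —
a change, since the baseline combination regimen carries an add-on
antiplatelet with no coded indication. The other scripts in `examples/`
walk through the change taxonomy and agreement statistics, a full
simulated trial, and the stepwise analysis.

A thin CLI wires the same functions into a reproducible pipeline
(`carat simulate --seed 1 -o out/`, then `score`, `recommend`,
`classify`, `agree`, `analyze`); every run writes a manifest with the
seed and config hash beside its output.

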