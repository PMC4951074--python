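"""Rule-based antithrombotic therapy recommendation.

The tool weighs a patient's stroke-risk category against their
bleeding-risk category and medication-safety checklist and recommends one
of warfarin, aspirin, no therapy, or "other". Novel oral anticoagulants
are never recommended (they were not selectable treatment options in the
tool; at most they appear in data as baseline or GP-chosen therapy).

The decision logic is a declarative, ordered rule cascade; the first rule
whose conditions all hold supplies the therapy and its rationale code.
The default cascade:

1. allergy to both warfarin and aspirin, or a documented contraindication
   to antithrombotics -> no therapy;
2. a warfarin-specific problem (adverse reaction, failed therapy,
   interacting medication) -> aspirin;
3. stroke risk intermediate/high and bleeding risk low/intermediate ->
   warfarin;
4. stroke risk intermediate/high and bleeding risk high -> aspirin;
5. stroke risk low and bleeding risk high -> no therapy;
6. stroke risk low otherwise -> aspirin.

Checklist items that describe management burden (cognitive impairment,
nonadherence, needing assistance, previously declined therapy, ...) do not
alter the risk-based recommendation; they are attached to the output as
flags for the prescriber to weigh. The cascade can be replaced wholesale
by loading an alternative rules file (JSON).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Optional, Sequence

from pydantic import BaseModel, ConfigDict

from .records import PatientRecord, Regimen, SafetyChecklist
from .scoring import RiskAssessment, RiskCategory, assess_risk

#: Stable code book mirroring the safety checklist; flag order follows
#: checklist field order.
SAFETY_CODES: dict[str, str] = {
    name: name.upper() for name in SafetyChecklist.model_fields
}

#: Therapies the tool can recommend (regimen level).
RECOMMENDABLE = (Regimen.warfarin, Regimen.aspirin_only, Regimen.none, Regimen.other)


class Recommendation(BaseModel):
    model_config = ConfigDict(extra="forbid")

    therapy: Regimen
    rationale: list[str]
    flags: list[str]
    change_required: bool
    dose_adjust: bool


@dataclass(frozen=True)
class Rule:
    """One leaf of the cascade.

    A rule fires when the stroke/bleed categories fall in the configured
    sets (``None`` = any) and, if ``safety_any`` is given, at least one of
    those checklist fields is true.
    """

    name: str
    therapy: Regimen
    code: str
    stroke_in: Optional[frozenset[RiskCategory]] = None
    bleed_in: Optional[frozenset[RiskCategory]] = None
    safety_any: tuple[str, ...] = ()

    def matches(self, assessment: RiskAssessment, safety: SafetyChecklist) -> bool:
        if self.stroke_in is not None and assessment.stroke_category not in self.stroke_in:
            return False
        if self.bleed_in is not None and assessment.bleed_category not in self.bleed_in:
            return False
        if self.safety_any and not any(getattr(safety, f) for f in self.safety_any):
            return False
        return True

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "therapy": self.therapy.value,
            "code": self.code,
            "stroke_in": sorted(c.value for c in self.stroke_in) if self.stroke_in else None,
            "bleed_in": sorted(c.value for c in self.bleed_in) if self.bleed_in else None,
            "safety_any": list(self.safety_any),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Rule":
        return cls(
            name=d["name"],
            therapy=Regimen(d["therapy"]),
            code=d["code"],
            stroke_in=frozenset(RiskCategory(c) for c in d["stroke_in"]) if d.get("stroke_in") else None,
            bleed_in=frozenset(RiskCategory(c) for c in d["bleed_in"]) if d.get("bleed_in") else None,
            safety_any=tuple(d.get("safety_any") or ()),
        )


_ALL = frozenset(RiskCategory)
_HI_INT = frozenset({RiskCategory.high, RiskCategory.intermediate})
_LOW_INT = frozenset({RiskCategory.low, RiskCategory.intermediate})
_HIGH = frozenset({RiskCategory.high})
_LOW = frozenset({RiskCategory.low})

DEFAULT_RULES: tuple[Rule, ...] = (
    Rule(
        "no_antithrombotic_tolerated",
        Regimen.none,
        "CONTRAINDICATED_ALL",
        safety_any=("allergy_warfarin_aspirin", "contraindication"),
    ),
    Rule(
        "warfarin_unsuitable",
        Regimen.aspirin_only,
        "WARFARIN_UNSUITABLE",
        safety_any=("adverse_reaction", "failed_therapy", "interacting_medication"),
    ),
    Rule(
        "stroke_risk_dominates",
        Regimen.warfarin,
        "STROKE_RISK_DOMINANT",
        stroke_in=_HI_INT,
        bleed_in=_LOW_INT,
    ),
    Rule(
        "high_bleed_tempers",
        Regimen.aspirin_only,
        "HIGH_BLEED_RISK",
        stroke_in=_HI_INT,
        bleed_in=_HIGH,
    ),
    Rule(
        "low_benefit_high_harm",
        Regimen.none,
        "LOW_STROKE_HIGH_BLEED",
        stroke_in=_LOW,
        bleed_in=_HIGH,
    ),
    Rule(
        "low_stroke_risk",
        Regimen.aspirin_only,
        "LOW_STROKE_RISK",
        stroke_in=_LOW,
    ),
)


@dataclass
class RuleSet:
    rules: tuple[Rule, ...] = field(default_factory=lambda: DEFAULT_RULES)

    def first_match(self, assessment: RiskAssessment, safety: SafetyChecklist) -> Rule:
        for rule in self.rules:
            if rule.matches(assessment, safety):
                return rule
        raise LookupError(
            "rule cascade is not total: no rule matched "
            f"(stroke={assessment.stroke_category}, bleed={assessment.bleed_category})"
        )

    def is_total(self) -> bool:
        """Exhaustively check that every (stroke, bleed, gate-flag) combination reaches a leaf."""
        gate_fields = sorted({f for r in self.rules for f in r.safety_any})
        for stroke, bleed in product(RiskCategory, RiskCategory):
            assessment = RiskAssessment(
                chads2=0, hemorrhages=0, stroke_category=stroke, bleed_category=bleed
            )
            for bits in product((False, True), repeat=len(gate_fields)):
                safety = SafetyChecklist(**dict(zip(gate_fields, bits)))
                try:
                    self.first_match(assessment, safety)
                except LookupError:
                    return False
        return True

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"rules": [r.to_dict() for r in self.rules]}, indent=2),
            encoding="utf-8",
        )

    @classmethod
    def load(cls, path: str | Path) -> "RuleSet":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(rules=tuple(Rule.from_dict(r) for r in d["rules"]))


def assess(patient: PatientRecord, **kwargs) -> RiskAssessment:
    """Score a patient's stroke and bleeding risk (see :func:`carat.scoring.assess_risk`)."""
    return assess_risk(patient.stroke, patient.bleed, **kwargs)


def flag_safety(patient: PatientRecord) -> list[str]:
    """One stable-order code per true checklist item."""
    return [
        SAFETY_CODES[name]
        for name in SafetyChecklist.model_fields
        if getattr(patient.safety, name)
    ]


def recommend(
    patient: PatientRecord,
    assessment: Optional[RiskAssessment] = None,
    rules: Optional[RuleSet | Sequence[Rule]] = None,
) -> Recommendation:
    """Run the cascade for one patient.

    ``change_required`` compares the recommended regimen with the baseline
    regimen. A dose adjustment (baseline warfarin kept, but the recorded
    INR control is sub-therapeutic) is not a regimen change:
    ``dose_adjust`` is set and ``change_required`` stays False.
    """
    if assessment is None:
        assessment = assess(patient)
    if rules is None:
        ruleset = RuleSet()
    elif isinstance(rules, RuleSet):
        ruleset = rules
    else:
        ruleset = RuleSet(rules=tuple(rules))

    rule = ruleset.first_match(assessment, patient.safety)
    therapy = rule.therapy
    change_required = therapy != patient.baseline_therapy
    dose_adjust = False
    if (
        therapy is Regimen.warfarin
        and patient.baseline_therapy is Regimen.warfarin
        and patient.inr_subtherapeutic
    ):
        dose_adjust = True
    return Recommendation(
        therapy=therapy,
        rationale=[rule.code],
        flags=flag_safety(patient),
        change_required=change_required,
        dose_adjust=dose_adjust,
    )
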