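"""CHADS2 stroke-risk and HEMORR2HAGES bleeding-risk scoring.

CHADS2 is the additive stroke-risk score for atrial fibrillation:
congestive heart failure, hypertension, age >= 75 and diabetes each score
one point; prior stroke or transient ischemic attack scores two, for a
0-6 range.

HEMORR2HAGES is the additive bleeding-risk score; every component scores
one point except re-bleeding risk, which scores two. The registry variant
used here collects nine of the eleven published components; the remaining
two (older age, genetic factors) can be switched on with
``include_extensions=True``, extending the range from 0-10 to 0-12.

Both scores map to low / intermediate / high categories through
configurable cutpoints. The defaults follow the scores' published
bandings (CHADS2: 0 low, 1 intermediate, >=2 high; HEMORR2HAGES: 0-1 low,
2-3 intermediate, >=4 high); the source trial states the categories but
not its exact cutpoints, so these are documented assumptions.
"""

from __future__ import annotations

import enum

from pydantic import BaseModel, ConfigDict, Field

from .records import BleedRiskFactors, StrokeRiskFactors

CHADS2_WEIGHTS: dict[str, int] = {
    "chf": 1,
    "hypertension": 1,
    "age_ge_75": 1,
    "diabetes": 1,
    "prior_stroke_or_tia": 2,
}

#: Core components collected by the registry (re-bleed doubled).
HEMORRHAGES_WEIGHTS: dict[str, int] = {
    "hepatic_or_renal": 1,
    "alcohol_abuse": 1,
    "malignancy": 1,
    "reduced_platelets": 1,
    "rebleed_risk": 2,
    "uncontrolled_htn": 1,
    "anemia": 1,
    "falls_risk": 1,
    "prior_hemorrhagic_stroke": 1,
}

#: Optional components of the full published score, off by default.
HEMORRHAGES_EXTENSION_WEIGHTS: dict[str, int] = {
    "age_gt_75": 1,
    "genetic_factor": 1,
}

CHADS2_MAX = sum(CHADS2_WEIGHTS.values())
HEMORRHAGES_MAX = sum(HEMORRHAGES_WEIGHTS.values()) + sum(
    HEMORRHAGES_EXTENSION_WEIGHTS.values()
)

#: (low-upper-exclusive, intermediate-upper-exclusive) score cutpoints.
DEFAULT_STROKE_CUTPOINTS = (1, 2)
DEFAULT_BLEED_CUTPOINTS = (2, 4)


class RiskCategory(str, enum.Enum):
    low = "low"
    intermediate = "intermediate"
    high = "high"


class RiskAssessment(BaseModel):
    """Joint stroke/bleeding assessment for one patient."""

    model_config = ConfigDict(extra="forbid")

    chads2: int = Field(ge=0, le=CHADS2_MAX)
    hemorrhages: int = Field(ge=0, le=HEMORRHAGES_MAX)
    stroke_category: RiskCategory
    bleed_category: RiskCategory


def compute_chads2(factors: StrokeRiskFactors) -> int:
    """Weighted sum of the five CHADS2 components (0-6)."""
    return sum(w for name, w in CHADS2_WEIGHTS.items() if getattr(factors, name))


def compute_hemorrhages(
    factors: BleedRiskFactors, include_extensions: bool = False
) -> int:
    """Weighted sum of the HEMORR2HAGES components.

    With ``include_extensions=False`` (default) the older-age and
    genetic-factor components are ignored even if set, matching the
    registry variant of the score.
    """
    score = sum(w for name, w in HEMORRHAGES_WEIGHTS.items() if getattr(factors, name))
    if include_extensions:
        score += sum(
            w
            for name, w in HEMORRHAGES_EXTENSION_WEIGHTS.items()
            if getattr(factors, name)
        )
    return score


def _categorize(
    score: int, cutpoints: tuple[int, int], upper: int, label: str
) -> RiskCategory:
    if not 0 <= score <= upper:
        raise ValueError(f"{label} score {score} outside [0, {upper}]")
    lo, hi = cutpoints
    if not 0 < lo < hi:
        raise ValueError(f"invalid cutpoints {cutpoints}: need 0 < low < high")
    if score < lo:
        return RiskCategory.low
    if score < hi:
        return RiskCategory.intermediate
    return RiskCategory.high


def categorize_stroke(
    score: int, cutpoints: tuple[int, int] = DEFAULT_STROKE_CUTPOINTS
) -> RiskCategory:
    """Band a CHADS2 score; defaults 0 low, 1 intermediate, >=2 high."""
    return _categorize(score, cutpoints, CHADS2_MAX, "CHADS2")


def categorize_bleed(
    score: int, cutpoints: tuple[int, int] = DEFAULT_BLEED_CUTPOINTS
) -> RiskCategory:
    """Band a HEMORR2HAGES score; defaults 0-1 low, 2-3 intermediate, >=4 high."""
    return _categorize(score, cutpoints, HEMORRHAGES_MAX, "HEMORR2HAGES")


def assess_risk(
    stroke: StrokeRiskFactors,
    bleed: BleedRiskFactors,
    *,
    include_extensions: bool = False,
    stroke_cutpoints: tuple[int, int] = DEFAULT_STROKE_CUTPOINTS,
    bleed_cutpoints: tuple[int, int] = DEFAULT_BLEED_CUTPOINTS,
) -> RiskAssessment:
    """Score both factor sets and band them into risk categories."""
    c = compute_chads2(stroke)
    h = compute_hemorrhages(bleed, include_extensions=include_extensions)
    return RiskAssessment(
        chads2=c,
        hemorrhages=h,
        stroke_category=categorize_stroke(c, stroke_cutpoints),
        bleed_category=categorize_bleed(h, bleed_cutpoints),
    )
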