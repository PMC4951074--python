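"""Synthetic cohort and prescriber-behavior simulator.

Generates patient registries with the statistical structure of a
cluster-randomized general-practice trial of antithrombotic prescribing:
general practitioners (GPs) are the clusters (default 25 per arm, each
recruiting 5-10 patients, with up to 20% dropout); baseline anticoagulant
use carries a configurable intracluster correlation (default 0.03); risk
factor, checklist and therapy marginals default to the registry's
observed prevalences.

Clustering construction: each GP receives an anticoagulant-prescribing
propensity drawn from a Beta distribution with mean equal to the arm's
anticoagulant probability ``p`` and shape sum ``a+b = (1-rho)/rho``. For
binary outcomes drawn Bernoulli(p_g) this yields an intraclass
correlation of exactly ``rho``, with no calibration step.

Risk factors are drawn independently per patient (the trial publishes
only marginals), with two exceptions: the age >= 75 flag is derived from
the drawn age, and uncontrolled hypertension is drawn only among
hypertensives so that its configured *marginal* prevalence is preserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats
from scipy.special import expit

from .changes import DISAGREEMENT_REASONS, AgreementRecord
from .engine import Recommendation
from .records import (
    AfibDuration,
    AfibType,
    Arm,
    BleedRiskFactors,
    HospitalizationReason,
    PatientRecord,
    Regimen,
    Rhythm,
    SafetyChecklist,
    Sex,
    StrokeRiskFactors,
)

_SUM_TOL = 1e-6


def _check_dist(d: dict, label: str) -> None:
    if any(not 0.0 <= p <= 1.0 for p in d.values()):
        raise ValueError(f"{label}: probabilities must lie in [0, 1]")
    if abs(sum(d.values()) - 1.0) > _SUM_TOL:
        raise ValueError(f"{label}: probabilities sum to {sum(d.values())}, not 1")


class GPBehavior(BaseModel):
    """How simulated GPs respond to the tool's recommendations."""

    model_config = ConfigDict(extra="forbid")

    p_accept: float = Field(default=0.752, ge=0.0, le=1.0)
    #: Given a *rejected* warfarin recommendation, probability the GP
    #: prescribes dabigatran instead (19 of the 22 rejected warfarin
    #: recommendations in the source trial).
    p_dabigatran_substitution: float = Field(default=19 / 22, ge=0.0, le=1.0)
    #: Final therapy when a warfarin rejection is not a dabigatran
    #: substitution (2 aspirin vs 1 none in the source trial).
    warfarin_rejection_fallback: dict[str, float] = Field(
        default_factory=lambda: {"aspirin_only": 2 / 3, "none": 1 / 3}
    )
    #: Final therapy when an aspirin/no-therapy recommendation is rejected.
    other_rejection_fallback: dict[str, float] = Field(
        default_factory=lambda: {"warfarin": 0.5, "dabigatran": 0.5}
    )
    reason_probs: dict[str, float] = Field(
        default_factory=lambda: {
            "inappropriate": 0.30,
            "cardiologist": 0.25,
            "familiarization_program": 0.20,
            "patient_refusal": 0.16,
            "other": 0.09,
        }
    )

    @model_validator(mode="after")
    def _valid(self) -> "GPBehavior":
        _check_dist(self.warfarin_rejection_fallback, "warfarin_rejection_fallback")
        _check_dist(self.other_rejection_fallback, "other_rejection_fallback")
        _check_dist(self.reason_probs, "reason_probs")
        for r in self.reason_probs:
            if r not in DISAGREEMENT_REASONS:
                raise ValueError(f"unknown disagreement reason {r!r}")
        return self


def _default_stroke_prevalences() -> dict[str, float]:
    return {
        "chf": 0.254,
        "hypertension": 0.682,
        "diabetes": 0.198,
        "prior_stroke_or_tia": 0.183,
    }


def _default_bleed_prevalences() -> dict[str, float]:
    # uncontrolled_htn is a *marginal* prevalence; it is realized only
    # among hypertensive patients.
    return {
        "hepatic_or_renal": 0.046,
        "alcohol_abuse": 0.020,
        "malignancy": 0.084,
        "reduced_platelets": 0.015,
        "rebleed_risk": 0.010,
        "uncontrolled_htn": 0.102,
        "anemia": 0.036,
        "falls_risk": 0.056,
        "prior_hemorrhagic_stroke": 0.015,
    }


def _default_safety_prevalences() -> dict[str, float]:
    return {
        "allergy_warfarin_aspirin": 0.020,
        "adverse_reaction": 0.038,
        "interacting_medication": 0.003,
        "declined_therapy": 0.013,
        "contraindication": 0.028,
        "failed_therapy": 0.025,
        "educated": 0.967,
        "noncompliant": 0.056,
        "needs_assistance": 0.410,
        "access_difficulty": 0.008,
        "residential_care": 0.010,
        "cognitive_impairment": 0.046,
        "vision_impairment": 0.061,
        "hearing_impairment": 0.087,
        "language_barrier": 0.010,
        "mobility_disorder": 0.043,
        "functional_impairment": 0.160,
    }


def _default_baseline_therapy() -> dict[str, dict[str, float]]:
    # Baseline regimen-group counts per arm: warfarin (+/- antiplatelet),
    # aspirin only, clopidogrel only, dabigatran (+/- clopidogrel), none.
    intervention = {"warfarin": 154, "aspirin_only": 17, "clopidogrel_only": 3, "dabigatran": 30, "none": 2}
    control = {"warfarin": 162, "aspirin_only": 6, "clopidogrel_only": 0, "dabigatran": 15, "none": 4}
    return {
        arm: {k: v / sum(counts.values()) for k, v in counts.items()}
        for arm, counts in (("intervention", intervention), ("control", control))
    }


class SimulationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_gps_per_arm: int = Field(default=25, ge=1)
    patients_per_gp: tuple[int, int] = (5, 10)
    icc: float = Field(default=0.03, ge=0.0, lt=1.0)
    dropout: float = Field(default=0.20, ge=0.0, lt=1.0)

    age_mean: float = 78.0
    age_sd: float = 7.0
    age_min: int = 65

    # (mean, sd) per arm for the count variables
    chronic_conditions: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {"intervention": (6.1, 2.7), "control": (5.4, 2.3)}
    )
    rx_meds: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {"intervention": (9.0, 3.7), "control": (9.4, 4.3)}
    )
    otc_meds: tuple[float, float] = (1.5, 1.3)

    p_male: float = 0.545
    stroke_prevalences: dict[str, float] = Field(default_factory=_default_stroke_prevalences)
    bleed_prevalences: dict[str, float] = Field(default_factory=_default_bleed_prevalences)
    safety_prevalences: dict[str, float] = Field(default_factory=_default_safety_prevalences)

    afib_duration_probs: dict[str, float] = Field(
        default_factory=lambda: {"lt_3mo": 0.025, "lt_12mo": 0.099, "lt_2y": 0.150, "lt_5y": 0.209, "ge_5y": 0.517}
    )
    afib_type_probs: dict[str, float] = Field(
        default_factory=lambda: {"paroxysmal": 0.354, "persistent": 0.570, "new_onset": 0.056, "unknown": 0.020}
    )
    p_prior_hospitalization: float = 0.341
    hospitalization_reason_probs: dict[str, float] = Field(
        default_factory=lambda: {"af_management": 0.649, "stroke": 0.179, "tia": 0.090, "other": 0.082}
    )
    rhythm_probs: dict[str, float] = Field(
        default_factory=lambda: {"sinus": 0.1145, "controlled_af": 0.8830, "uncontrolled_af": 0.0025}
    )

    baseline_therapy_distribution: dict[str, dict[str, float]] = Field(
        default_factory=_default_baseline_therapy
    )
    #: Within the warfarin group, probability of an add-on antiplatelet
    #: (16 of 316 warfarin users in the source registry).
    p_combo_given_warfarin: float = Field(default=16 / 316, ge=0.0, le=1.0)
    p_clopidogrel_given_dabigatran: float = Field(default=0.0, ge=0.0, le=1.0)
    #: Among baseline warfarin users, probability the INR is recorded as
    #: sub-therapeutic (drives the single dose-adjust recommendation).
    p_inr_subtherapeutic: float = Field(default=1 / 154, ge=0.0, le=1.0)

    gp_behavior: GPBehavior = Field(default_factory=GPBehavior)
    seed: int = 0

    @model_validator(mode="after")
    def _valid(self) -> "SimulationConfig":
        lo, hi = self.patients_per_gp
        if not 1 <= lo <= hi:
            raise ValueError(f"invalid patients_per_gp range {self.patients_per_gp}")
        for label, d in (
            ("afib_duration_probs", self.afib_duration_probs),
            ("afib_type_probs", self.afib_type_probs),
            ("hospitalization_reason_probs", self.hospitalization_reason_probs),
            ("rhythm_probs", self.rhythm_probs),
        ):
            _check_dist(d, label)
        for arm, d in self.baseline_therapy_distribution.items():
            _check_dist(d, f"baseline_therapy_distribution[{arm}]")
        for label, d in (
            ("stroke_prevalences", self.stroke_prevalences),
            ("bleed_prevalences", self.bleed_prevalences),
            ("safety_prevalences", self.safety_prevalences),
        ):
            if any(not 0.0 <= p <= 1.0 for p in d.values()):
                raise ValueError(f"{label}: probabilities must lie in [0, 1]")
        return self


def _beta_params(mean: float, rho: float) -> tuple[float, float]:
    total = (1.0 - rho) / rho
    return mean * total, (1.0 - mean) * total


def _draw_categorical(rng: np.random.Generator, probs: dict[str, float], size: int) -> np.ndarray:
    keys = list(probs)
    p = np.asarray([probs[k] for k in keys], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(keys), size=size, p=p)
    return np.asarray(keys, dtype=object)[idx]


def _draw_count(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    return np.clip(np.round(rng.normal(mean, sd, size)), 0, None).astype(int)


def generate_cohort(
    config: Optional[SimulationConfig] = None, seed: Optional[int] = None
) -> list[PatientRecord]:
    """Generate a two-arm clustered cohort; reproducible for a fixed seed."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    records: list[PatientRecord] = []
    pid = 0

    for arm in (Arm.intervention, Arm.control):
        therapy_probs = cfg.baseline_therapy_distribution[arm.value]
        p_ac = therapy_probs["warfarin"] + therapy_probs["dabigatran"]
        lo, hi = cfg.patients_per_gp
        sizes = rng.integers(lo, hi + 1, size=cfg.n_gps_per_arm)
        n_arm = int(sizes.sum())
        gp_ids = np.repeat(
            [f"{arm.value[0]}gp{g:03d}" for g in range(cfg.n_gps_per_arm)], sizes
        )

        # GP-level anticoagulant propensity (beta-binomial cluster effect)
        if cfg.icc > 0.0 and 0.0 < p_ac < 1.0:
            a, b = _beta_params(p_ac, cfg.icc)
            p_g = np.repeat(rng.beta(a, b, size=cfg.n_gps_per_arm), sizes)
        else:
            p_g = np.full(n_arm, p_ac)
        anticoag = rng.random(n_arm) < p_g

        # Regimen conditional on anticoagulant-vs-not
        u = rng.random(n_arm)
        v = rng.random(n_arm)
        regimens = np.empty(n_arm, dtype=object)
        p_warf_given_ac = therapy_probs["warfarin"] / p_ac if p_ac > 0 else 0.0
        for i in range(n_arm):
            if anticoag[i]:
                if u[i] < p_warf_given_ac:
                    regimens[i] = (
                        Regimen.warfarin_plus_antiplatelet
                        if v[i] < cfg.p_combo_given_warfarin
                        else Regimen.warfarin
                    )
                else:
                    regimens[i] = (
                        Regimen.dabigatran_plus_clopidogrel
                        if v[i] < cfg.p_clopidogrel_given_dabigatran
                        else Regimen.dabigatran
                    )
            else:
                p_rest = 1.0 - p_ac
                cum = 0.0
                regimens[i] = Regimen.none
                for key, reg in (
                    ("aspirin_only", Regimen.aspirin_only),
                    ("clopidogrel_only", Regimen.clopidogrel_only),
                    ("none", Regimen.none),
                ):
                    cum += therapy_probs[key] / p_rest if p_rest > 0 else 0.0
                    if u[i] < cum:
                        regimens[i] = reg
                        break

        a_trunc = (cfg.age_min - cfg.age_mean) / cfg.age_sd
        ages = np.round(
            stats.truncnorm.rvs(
                a_trunc, np.inf, loc=cfg.age_mean, scale=cfg.age_sd,
                size=n_arm, random_state=rng,
            )
        ).astype(int)
        sexes = rng.random(n_arm) < cfg.p_male
        chronic = _draw_count(rng, *cfg.chronic_conditions[arm.value], n_arm)
        rx = _draw_count(rng, *cfg.rx_meds[arm.value], n_arm)
        otc = _draw_count(rng, *cfg.otc_meds, n_arm)

        stroke_draws = {
            k: rng.random(n_arm) < p for k, p in cfg.stroke_prevalences.items()
        }
        bleed_draws = {
            k: rng.random(n_arm) < p
            for k, p in cfg.bleed_prevalences.items()
            if k != "uncontrolled_htn"
        }
        # realized only among hypertensives, preserving the marginal
        p_htn = cfg.stroke_prevalences.get("hypertension", 0.0)
        p_unc = cfg.bleed_prevalences.get("uncontrolled_htn", 0.0)
        p_unc_cond = min(1.0, p_unc / p_htn) if p_htn > 0 else 0.0
        bleed_draws["uncontrolled_htn"] = stroke_draws["hypertension"] & (
            rng.random(n_arm) < p_unc_cond
        )
        safety_draws = {
            k: rng.random(n_arm) < p for k, p in cfg.safety_prevalences.items()
        }

        duration = _draw_categorical(rng, cfg.afib_duration_probs, n_arm)
        af_type = _draw_categorical(rng, cfg.afib_type_probs, n_arm)
        hosp = rng.random(n_arm) < cfg.p_prior_hospitalization
        hosp_reason = _draw_categorical(rng, cfg.hospitalization_reason_probs, n_arm)
        rhythm = _draw_categorical(rng, cfg.rhythm_probs, n_arm)
        inr_draw = rng.random(n_arm) < cfg.p_inr_subtherapeutic
        keep = rng.random(n_arm) >= cfg.dropout

        for i in range(n_arm):
            if not keep[i]:
                continue
            pid += 1
            reg = regimens[i]
            on_warfarin = reg in (Regimen.warfarin, Regimen.warfarin_plus_antiplatelet)
            records.append(
                PatientRecord(
                    patient_id=f"p{pid:05d}",
                    gp_id=str(gp_ids[i]),
                    arm=arm,
                    age=int(ages[i]),
                    sex=Sex.male if sexes[i] else Sex.female,
                    chronic_condition_count=int(chronic[i]),
                    rx_med_count=int(rx[i]),
                    otc_med_count=int(otc[i]),
                    afib_duration=AfibDuration(duration[i]),
                    afib_type=AfibType(af_type[i]),
                    prior_hospitalization=bool(hosp[i]),
                    hospitalization_reason=(
                        HospitalizationReason(hosp_reason[i]) if hosp[i] else None
                    ),
                    rhythm=Rhythm(rhythm[i]),
                    stroke=StrokeRiskFactors(
                        age_ge_75=bool(ages[i] >= 75),
                        **{k: bool(vv[i]) for k, vv in stroke_draws.items()},
                    ),
                    bleed=BleedRiskFactors(
                        **{k: bool(vv[i]) for k, vv in bleed_draws.items()}
                    ),
                    safety=SafetyChecklist(
                        polypharmacy_ge4=bool(rx[i] >= 4),
                        **{k: bool(vv[i]) for k, vv in safety_draws.items()},
                    ),
                    baseline_therapy=reg,
                    inr_subtherapeutic=bool(inr_draw[i]) if on_warfarin else None,
                )
            )
    return records


def simulate_gp_decisions(
    cohort: Sequence[PatientRecord],
    recommendations: Sequence[Recommendation],
    behavior: Optional[GPBehavior] = None,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[AgreementRecord]:
    """Draw each GP's final decision given the tool's recommendation.

    A recommendation is accepted with probability ``p_accept``. A rejected
    warfarin recommendation becomes dabigatran with probability
    ``p_dabigatran_substitution``, otherwise a draw from the warfarin
    fallback mixture; rejected aspirin/no-therapy recommendations draw
    from the other fallback mixture (excluding the recommended regimen).
    Disagreements carry a sampled reason code.
    """
    if len(cohort) != len(recommendations):
        raise ValueError(
            f"{len(cohort)} patients but {len(recommendations)} recommendations"
        )
    beh = behavior or GPBehavior()
    if rng is None:
        rng = np.random.default_rng(seed)
    out: list[AgreementRecord] = []
    for rec in recommendations:
        if rng.random() < beh.p_accept:
            out.append(AgreementRecord.from_pair(rec.therapy, rec.therapy))
            continue
        if rec.therapy is Regimen.warfarin:
            if rng.random() < beh.p_dabigatran_substitution:
                final = Regimen.dabigatran
            else:
                final = Regimen(_sample_excluding(rng, beh.warfarin_rejection_fallback, rec.therapy))
        else:
            final = Regimen(_sample_excluding(rng, beh.other_rejection_fallback, rec.therapy))
        reason = str(_draw_categorical(rng, beh.reason_probs, 1)[0])
        out.append(AgreementRecord.from_pair(rec.therapy, final, disagreement_reason=reason))
    return out


def _sample_excluding(
    rng: np.random.Generator, probs: dict[str, float], exclude: Regimen
) -> str:
    d = {k: p for k, p in probs.items() if Regimen(k) is not exclude}
    if not d:
        raise ValueError("rejection mixture excludes every option")
    return str(_draw_categorical(rng, d, 1)[0])


@dataclass
class ICCResult:
    estimate: float
    n_clusters: int
    n: int
    ms_between: float
    ms_within: float
    degenerate: bool = False


def estimate_icc(cluster_ids: Sequence, outcome: Sequence[float]) -> ICCResult:
    """One-way ANOVA intraclass-correlation estimator for a (binary) outcome.

    Returns the usual ``(MSB - MSW) / (MSB + (n0 - 1) MSW)`` moment
    estimate, which can be negative in small samples. A constant outcome
    is degenerate (estimate NaN, flagged); clusters must not all be
    singletons.
    """
    ids = np.asarray(cluster_ids)
    y = np.asarray(outcome, dtype=float)
    if ids.shape != y.shape:
        raise ValueError("cluster ids and outcome differ in length")
    labels, inverse = np.unique(ids, return_inverse=True)
    k = len(labels)
    n = len(y)
    if k < 2:
        raise ValueError("need at least 2 clusters")
    sizes = np.bincount(inverse)
    if sizes.max() < 2:
        raise ValueError("all clusters are singletons; ICC undefined")
    if np.all(y == y[0]):
        return ICCResult(math.nan, k, n, 0.0, 0.0, degenerate=True)

    grand = y.mean()
    cluster_sums = np.bincount(inverse, weights=y)
    cluster_means = cluster_sums / sizes
    ssb = float(np.sum(sizes * (cluster_means - grand) ** 2))
    ssw = float(np.sum((y - cluster_means[inverse]) ** 2))
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    n0 = (n - np.sum(sizes**2) / n) / (k - 1)
    denom = msb + (n0 - 1.0) * msw
    if denom <= 0:
        return ICCResult(math.nan, k, n, msb, msw, degenerate=True)
    return ICCResult((msb - msw) / denom, k, n, msb, msw)


def simulate_clustered_binary(
    cluster_ids: Sequence,
    linear_predictor: Sequence[float],
    icc: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bernoulli outcomes from a logistic model with a cluster random intercept.

    The random-intercept variance is set to ``icc/(1-icc) * pi^2/3`` so
    the latent-scale intraclass correlation equals ``icc``.
    """
    ids = np.asarray(cluster_ids)
    eta = np.asarray(linear_predictor, dtype=float)
    labels, inverse = np.unique(ids, return_inverse=True)
    sigma = math.sqrt(icc / (1.0 - icc) * math.pi**2 / 3.0) if icc > 0 else 0.0
    u = rng.normal(0.0, sigma, size=len(labels)) if sigma > 0 else np.zeros(len(labels))
    p = expit(eta + u[inverse])
    return (rng.random(len(eta)) < p).astype(int)
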