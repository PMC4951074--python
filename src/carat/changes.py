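"""Therapy-transition taxonomy, agreement statistics, and therapy summaries.

A transition between antithrombotic regimens is classified on the
effectiveness ordering ``none < antiplatelet < anticoagulant``:

* **upgrade** — therapy class rises (e.g. no therapy to any agent, or
  aspirin to warfarin);
* **side-step** — class unchanged but the regimen differs (e.g. one
  anticoagulant to another, or warfarin+aspirin to warfarin only);
* **downgrade** — class falls (e.g. any agent to no therapy, or an
  anticoagulant to aspirin);
* **dose_adjust** — same regimen, dose changed (the warfarin INR-target
  case);
* **no_change** — identical regimen, no dose change.

Agreement between the tool's recommendation and the prescriber's final
decision is summarised as raw percent agreement (regimen level and
therapy-class level) and as the Fleiss kappa chance-corrected statistic.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .records import Regimen, TherapyClass, primary_agent, therapy_class

CLASS_RANK: dict[TherapyClass, int] = {
    TherapyClass.none: 0,
    TherapyClass.antiplatelet: 1,
    TherapyClass.anticoagulant: 2,
}

DISAGREEMENT_REASONS = (
    "inappropriate",
    "cardiologist",
    "familiarization_program",
    "patient_refusal",
    "other",
)


class ChangeClass(str, enum.Enum):
    no_change = "no_change"
    upgrade = "upgrade"
    side_step = "side_step"
    downgrade = "downgrade"
    dose_adjust = "dose_adjust"


class UnrankableRegimenError(ValueError):
    """Transition involves an 'other' regimen with no configured rank."""


def classify_change(
    baseline: Regimen | str,
    target: Regimen | str,
    dose_changed: bool = False,
    other_rank: Optional[int] = None,
) -> ChangeClass:
    """Classify one baseline -> target transition.

    ``other_rank`` optionally places the unrankable "other" class on the
    effectiveness ordering; without it any transition touching "other"
    raises :class:`UnrankableRegimenError`.
    """
    baseline, target = Regimen(baseline), Regimen(target)
    if baseline == target:
        return ChangeClass.dose_adjust if dose_changed else ChangeClass.no_change

    def rank(r: Regimen) -> int:
        cls = therapy_class(r)
        if cls is TherapyClass.other:
            if other_rank is None:
                raise UnrankableRegimenError(
                    f"cannot rank regimen {r.value!r}; supply other_rank"
                )
            return other_rank
        return CLASS_RANK[cls]

    rb, rt = rank(baseline), rank(target)
    if rt > rb:
        return ChangeClass.upgrade
    if rt < rb:
        return ChangeClass.downgrade
    return ChangeClass.side_step


@dataclass
class ChangeTabulation:
    """Counts per change class plus percentages over the changed subset.

    Percentages are computed over upgrades + side-steps + downgrades only
    (dose adjustments and unchanged therapy excluded from the
    denominator), rounded to one decimal. With no changes the percentages
    are undefined and reported as ``None``.
    """

    counts: dict[ChangeClass, int]
    n: int
    n_changes: int
    percent_of_changes: Optional[dict[ChangeClass, float]]

    def __getitem__(self, key: ChangeClass) -> int:
        return self.counts[key]


_CHANGED = (ChangeClass.upgrade, ChangeClass.side_step, ChangeClass.downgrade)


def tabulate_changes(
    transitions: Sequence[tuple[Regimen | str, Regimen | str, bool]],
    other_rank: Optional[int] = None,
) -> ChangeTabulation:
    """Classify and tally a list of (baseline, target, dose_changed) transitions."""
    if len(transitions) == 0:
        raise ValueError("cannot tabulate an empty transition list")
    counts = {c: 0 for c in ChangeClass}
    for baseline, target, dose_changed in transitions:
        counts[classify_change(baseline, target, dose_changed, other_rank)] += 1
    n_changes = sum(counts[c] for c in _CHANGED)
    if n_changes == 0:
        percents = None
    else:
        percents = {c: round(100.0 * counts[c] / n_changes, 1) for c in _CHANGED}
    return ChangeTabulation(
        counts=counts, n=len(transitions), n_changes=n_changes, percent_of_changes=percents
    )


class AgreementRecord(BaseModel):
    """Tool recommendation vs prescriber final decision for one patient."""

    model_config = ConfigDict(extra="forbid")

    carat_therapy: Regimen
    gp_final_therapy: Regimen
    agree_overall: bool
    agree_class: bool
    agree_agent: bool
    disagreement_reason: Optional[str] = None

    @model_validator(mode="after")
    def _consistent(self) -> "AgreementRecord":
        if self.agree_overall != (self.carat_therapy == self.gp_final_therapy):
            raise ValueError("agree_overall must mean identical regimens")
        if self.agree_agent and not self.agree_class:
            raise ValueError("agreement on agent implies agreement on class")
        if self.disagreement_reason is not None and self.disagreement_reason not in DISAGREEMENT_REASONS:
            raise ValueError(f"unknown disagreement reason {self.disagreement_reason!r}")
        return self

    @classmethod
    def from_pair(
        cls,
        carat_therapy: Regimen | str,
        gp_final_therapy: Regimen | str,
        disagreement_reason: Optional[str] = None,
    ) -> "AgreementRecord":
        c, g = Regimen(carat_therapy), Regimen(gp_final_therapy)
        return cls(
            carat_therapy=c,
            gp_final_therapy=g,
            agree_overall=c == g,
            agree_class=therapy_class(c) == therapy_class(g),
            agree_agent=primary_agent(c) == primary_agent(g),
            disagreement_reason=disagreement_reason,
        )


def percent_agreement(pairs: Sequence[AgreementRecord], level: str = "regimen") -> float:
    """Fraction of pairs agreeing at ``level`` in {"regimen", "class", "agent"}."""
    if len(pairs) == 0:
        raise ValueError("cannot compute agreement on an empty list")
    attr = {"regimen": "agree_overall", "class": "agree_class", "agent": "agree_agent"}[level]
    return sum(getattr(p, attr) for p in pairs) / len(pairs)


def tally_reasons(pairs: Iterable[AgreementRecord]) -> dict[str, int]:
    """Count disagreement-reason codes over disagreeing pairs only."""
    return dict(
        Counter(
            p.disagreement_reason
            for p in pairs
            if not p.agree_overall and p.disagreement_reason is not None
        )
    )


class DegenerateMarginsError(ValueError):
    """Chance agreement is 1 (a single category carries all mass)."""


def build_rating_table(
    ratings_a: Sequence[object], ratings_b: Sequence[object]
) -> tuple[np.ndarray, list[object]]:
    """Subject x category count table for two raters.

    Categories are the sorted set of values actually used by either rater
    (zero-margin categories from the wider enum are excluded so they do
    not distort chance agreement).
    """
    if len(ratings_a) != len(ratings_b):
        raise ValueError("rater vectors differ in length")
    cats = sorted({str(v) for v in ratings_a} | {str(v) for v in ratings_b})
    index = {c: j for j, c in enumerate(cats)}
    table = np.zeros((len(ratings_a), len(cats)), dtype=int)
    for i, (a, b) in enumerate(zip(ratings_a, ratings_b)):
        table[i, index[str(a)]] += 1
        table[i, index[str(b)]] += 1
    return table, cats


def fleiss_kappa(table: np.ndarray | Sequence[Sequence[int]]) -> float:
    """Fleiss' kappa for a subject x category table of rating counts.

    Every subject must be rated by the same number of raters (row sums
    equal, >= 2). Returns ``(P_bar - P_e) / (1 - P_e)`` where ``P_bar`` is
    the mean pairwise observed agreement and ``P_e`` the chance agreement
    from pooled category proportions. Raises
    :class:`DegenerateMarginsError` when ``P_e = 1``.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 1 or t.shape[1] < 2:
        raise ValueError("need a 2-D table with at least 2 categories")
    row_sums = t.sum(axis=1)
    n_raters = row_sums[0]
    if n_raters < 2 or not np.all(row_sums == n_raters):
        raise ValueError("every subject must be rated by the same n >= 2 raters")
    n_subjects = t.shape[0]
    p_j = t.sum(axis=0) / (n_subjects * n_raters)
    p_e = float(np.sum(p_j**2))
    p_i = (np.sum(t**2, axis=1) - n_raters) / (n_raters * (n_raters - 1))
    p_bar = float(np.mean(p_i))
    if p_e >= 1.0 - 1e-12:
        raise DegenerateMarginsError(
            "chance agreement is 1 (single-category marginals); kappa undefined"
        )
    return (p_bar - p_e) / (1.0 - p_e)


class AgreementResult(BaseModel):
    model_config = ConfigDict(extra="forbid")

    percent_agreement: float
    percent_class_agreement: float
    kappa: Optional[float]
    n: int
    reason_tally: dict[str, int]

    @model_validator(mode="after")
    def _bounds(self) -> "AgreementResult":
        if not 0.0 <= self.percent_agreement <= 1.0:
            raise ValueError("percent_agreement outside [0, 1]")
        if self.kappa is not None and not -1.0 <= self.kappa <= 1.0 + 1e-12:
            raise ValueError("kappa outside [-1, 1]")
        return self


def summarize_agreement(pairs: Sequence[AgreementRecord]) -> AgreementResult:
    """Percent agreement (regimen and class level), Fleiss kappa, reason tally.

    Kappa is computed over the regimen categories actually used; if the
    marginals are degenerate (everyone in one category) it is reported as
    ``None``.
    """
    table, _ = build_rating_table(
        [p.carat_therapy.value for p in pairs],
        [p.gp_final_therapy.value for p in pairs],
    )
    try:
        kappa: Optional[float] = fleiss_kappa(table)
    except (DegenerateMarginsError, ValueError):
        kappa = None
    return AgreementResult(
        percent_agreement=percent_agreement(pairs, "regimen"),
        percent_class_agreement=percent_agreement(pairs, "class"),
        kappa=kappa,
        n=len(pairs),
        reason_tally=tally_reasons(pairs),
    )


@dataclass
class TherapyDistribution:
    """Counts and percentages of regimens and therapy classes in a cohort."""

    n: int
    regimen_counts: dict[Regimen, int] = field(default_factory=dict)

    @property
    def class_counts(self) -> dict[TherapyClass, int]:
        out: dict[TherapyClass, int] = {c: 0 for c in TherapyClass}
        for r, k in self.regimen_counts.items():
            out[therapy_class(r)] += k
        return out

    @property
    def n_any_antithrombotic(self) -> int:
        return sum(
            k for r, k in self.regimen_counts.items() if therapy_class(r)
            in (TherapyClass.anticoagulant, TherapyClass.antiplatelet)
        )

    def pct(self, count: int, denominator: Optional[int] = None) -> float:
        """Percentage rounded to one decimal, over ``denominator`` (default n)."""
        d = self.n if denominator is None else denominator
        return round(100.0 * count / d, 1)

    @property
    def pct_any_antithrombotic(self) -> float:
        return self.pct(self.n_any_antithrombotic)

    @property
    def pct_anticoagulant(self) -> float:
        return self.pct(self.class_counts[TherapyClass.anticoagulant])

    @property
    def pct_antiplatelet(self) -> float:
        return self.pct(self.class_counts[TherapyClass.antiplatelet])

    def pct_agent_among_treated(self, agent: str) -> float:
        """Share of treated patients whose regimen is built on ``agent``."""
        k = sum(
            c for r, c in self.regimen_counts.items() if primary_agent(r) == agent
        )
        return self.pct(k, self.n_any_antithrombotic)


def therapy_distribution(regimens: Sequence[Regimen | str]) -> TherapyDistribution:
    if len(regimens) == 0:
        raise ValueError("empty regimen list")
    counts = Counter(Regimen(r) for r in regimens)
    return TherapyDistribution(n=len(regimens), regimen_counts=dict(counts))
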