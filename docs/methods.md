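# Methods

This note records the models, default parameters, numerical choices and
known limitations behind `carat`. Nothing here states a result the test
suite or `scripts/acceptance.py` does not itself compute.

## Risk scoring

CHADS₂ is the additive stroke-risk score for atrial fibrillation:
congestive heart failure 1, hypertension 1, age ≥ 75 years 1, diabetes
1, prior stroke or transient ischemic attack 2; range 0–6.
HEMORR₂HAGES is the additive bleeding-risk score; the re-bleeding
component scores 2 and all others 1. The registry variant implemented
by default collects nine components (hepatic or renal disease, alcohol
abuse, malignancy, reduced platelet count, re-bleeding risk,
uncontrolled hypertension, anemia, excessive falls risk, prior
hemorrhagic stroke; range 0–10); the two remaining components of the
full published score (older age, genetic factors) are carried as
optional fields and included only with `include_extensions=True`
(range 0–12).

Risk bands default to the scores' published groupings — CHADS₂ 0 low /
1 intermediate / ≥2 high; HEMORR₂HAGES 0–1 / 2–3 / ≥4 — and are
configurable cutpoints, because the banding used by the original
deployed tool is not recoverable from printed aggregates. The observed
band distributions (for example ~96% of a registry at low bleeding
risk) are consistent with these defaults. Both banding functions are
monotone step functions; out-of-range scores raise.

## Recommendation cascade

The original tool's full decision matrix is unpublished; the default
cascade here is a reconstruction that reproduces every aggregate
behavior the trial reports (some therapy recommended for every patient,
warfarin preferred, downgrades only on safety grounds, zero NOAC
recommendations). Rules are evaluated in order; the first match wins:

1. allergy to warfarin and aspirin, or documented contraindication to
   antithrombotics → none;
2. warfarin-specific problem (adverse reaction, failed therapy,
   interacting medication) → aspirin;
3. stroke risk ≥ intermediate and bleeding risk ≤ intermediate →
   warfarin;
4. stroke risk ≥ intermediate and bleeding risk high → aspirin;
5. stroke risk low and bleeding risk high → none;
6. stroke risk low otherwise → aspirin.

The cascade is total over (stroke band × bleed band × gate flags) —
verified exhaustively in tests — and externalized as a JSON rules file
so alternative reconstructions can be evaluated without code changes.
Management-burden checklist items (declined therapy, cognitive
impairment, nonadherence, assistance needs, …) never change the
risk-based leaf; they are emitted as flags, matching the observation
that patient refusal surfaced as a prescriber override reason rather
than a tool output. A dose adjustment (sub-therapeutic INR on baseline
warfarin with warfarin recommended) is reported via `dose_adjust` and
is not a regimen change. Open points decided here: the "other" therapy
leaf is reserved in the rules schema but unreachable by the default
cascade (no instance appears in the trial's printed distributions), and
intermediate-stroke/intermediate-bleed patients receive warfarin
(rule 3), which the printed aggregates cannot contradict.

## Change taxonomy and agreement

Transitions are classified on the effectiveness ordering none <
antiplatelet < anticoagulant; equal class with a different regimen is a
side-step. "Other" regimens are unrankable and raise unless a rank is
supplied; they are excluded from taxonomy tallies. Percentages in
`tabulate_changes` are taken over actual regimen changes only
(upgrades + side-steps + downgrades), rounded to one decimal; a
zero-change denominator is reported as undefined (`None`) rather than
0/0.

Agreement is reported at both the regimen level and the therapy-class
level, since a prescriber substituting one anticoagulant for another
agrees on class but not agent. Fleiss κ = (P̄ − P̄ₑ)/(1 − P̄ₑ) is
computed over the categories actually used by either rater — including
never-used enum values would deflate chance agreement — and degenerate
marginals (P̄ₑ = 1) are signalled explicitly. The implementation is the
closed-form formula; tests check it against a brute-force two-rater
counting oracle (to 10⁻¹⁰) and against statsmodels'
`inter_rater.fleiss_kappa`. Note that κ can only reach a printed raw
agreement from below (κ ≤ P̄₀ when P̄ₑ ≥ 0); published pairings that
violate this cannot be reproduced by any correct implementation.

## Trial statistics

Between-arm comparisons choose the test from the variable's type:
Pearson χ² without continuity correction for categorical variables,
switching to the two-sided Fisher exact test on 2×2 tables when any
expected cell is below 5; Welch's unequal-variance t (two groups) or
one-way ANOVA for continuous variables; Mann–Whitney U or
Kruskal–Wallis for ordinal ones. Constant variables raise a
degenerate-test error.

The Fisher exact p is computed directly: over the hypergeometric
support fixed by the margins, the probabilities of all outcomes not
exceeding the observed one (tie tolerance 1 + 10⁻⁷, the standard
convention) are summed, using vectorized log-binomial coefficients.
This keeps the exhaustive verification against exact integer
enumeration (all 635,375 tables with n ≤ 60) fast; scipy's
`fisher_exact` serves as an additional independent cross-check on
random tables.

Predictor selection mirrors the conventional stepwise workflow:
univariate logistic screening retains covariates with Wald p < 0.10
(constants excluded with a warning; separation flagged but retained),
then forward stepwise selection adds the candidate with the smallest
Wald p below the entry threshold (default 0.05) and removes included
terms whose Wald p exceeds the removal threshold (default 0.10). Ties
are broken by covariate name, making selection invariant to input
order; a visited-state set guarantees termination; candidates whose fit
fails (separation, |log-odds| > 15, singularity) are skipped and
recorded. Because treatment assignment is constant within a GP cluster,
plain logistic standard errors understate its sampling variance; the
final model's CIs therefore use a cluster-robust covariance over
`gp_id` when groups are supplied, falling back to the plain fit if the
robust fit fails (both paths are reported via `cluster_adjusted`).
Pseudo-R²: Cox–Snell = 1 − exp(2(LL₀ − LL₁)/n) and Nagelkerke =
Cox–Snell / (1 − exp(2LL₀/n)); Nagelkerke ≥ Cox–Snell always, and a
model log-likelihood below the null raises an invalid-fit error.
Classification rate is at the 0.5 probability cutoff.

## Synthetic cohorts

The generator emulates a two-arm, GP-clustered registry of AFib
patients aged ≥ 65. Defaults are the trial's stated design and observed
marginals: 25 GPs per arm, 5–10 patients per GP, intracluster
correlation 0.03 for baseline anticoagulant use, 20% dropout (applied
as post-generation removal); age truncated-normal (mean 78, SD 7,
floor 65); risk-factor, checklist and per-arm baseline-therapy
prevalences from the registry's tables (e.g. hypertension 0.682, age
≥ 75 implied ≈ 0.69 by the age distribution, prior stroke/TIA 0.183;
baseline anticoagulant use 89.3% intervention / 94.7% control).

Clustering uses a beta-binomial construction: each GP's anticoagulant
propensity is drawn from a Beta distribution with mean equal to the
arm's anticoagulant probability p and shape sum (1 − ρ)/ρ, which gives
a binary-outcome intraclass correlation of exactly ρ with no
calibration step. The regimen within the anticoagulant /
non-anticoagulant split is then drawn from the arm's conditional
distribution. The split of the dabigatran group into ±clopidogrel is
unprinted, so the default puts all its mass on dabigatran monotherapy;
within the warfarin group 16/316 carry an add-on antiplatelet.

Risk factors are otherwise independent across patients — the source
tables publish only marginals, so no correlation structure is asserted
— with two consistency exceptions: the age ≥ 75 flag is derived from
the drawn age, and uncontrolled hypertension is drawn only among
hypertensives at a conditional rate preserving its configured marginal.
The polypharmacy flag is likewise derived from the drawn prescription
count rather than being a free prevalence. Count variables use rounded
clipped normals with the per-arm printed means/SDs. Consequently,
passing tests show marginal and clustering calibration, not realistic
between-factor dependence; analyses relying on covariate correlation
structure should not treat the generator as evidence.

Simulated GPs accept a recommendation with probability 0.752; a
rejected warfarin recommendation becomes dabigatran with probability
19/22 (the trial's substitution pattern), otherwise aspirin (2/3) or
nothing (1/3); rejected aspirin/no-therapy recommendations draw
warfarin or dabigatran with equal probability — a choice, since that
branch is unprinted. Disagreement reasons are sampled from a fixed
distribution ordered like the trial's tallies (inappropriate 0.30,
cardiologist 0.25, familiarization program 0.20, patient refusal 0.16,
other 0.09).

The ICC estimator is the one-way ANOVA moment estimator
(MSB − MSW)/(MSB + (n₀ − 1)MSW); it is left unclipped (small-sample
estimates can be negative), degenerate outcomes are flagged, and
all-singleton clusterings raise. Round-trip validation estimates over
all 50 clusters of a two-arm cohort: with only 25 clusters the ratio
estimator has a noticeable downward bias, while pooling adds a small
(~+0.01) genuine component from the between-arm prevalence difference.

## Validation studies and problem sizes

The packaged studies (`carat.studies`) use sizes chosen to give stable
Monte-Carlo estimates on a laptop-class budget: odds-ratio recovery
runs 200 trials of 400 patients (50 clusters × 8), true intervention
OR 3 on a latent-ICC-0.03 logistic outcome, reporting the mean
recovered OR and cluster-robust 95% CI coverage; ICC recovery averages
100 replicates at ρ ∈ {0, 0.03, 0.3}; the no-NOAC check simulates
10,000 patients. The stepwise OR target is the *conditional* OR 3; with
random-intercept variance at ICC 0.03 the marginal attenuation is below
2%, well inside Monte-Carlo noise at these sizes.

## Known limitations

- The rule cascade is a faithful-in-aggregate reconstruction, not the
  original tool's unpublished matrix; alternative cascades can be
  loaded from JSON.
- Original trial coefficients (e.g. published multivariate odds ratios)
  require patient-level data and are not reproducible; the simulation
  studies validate the estimator pipeline instead.
- No NOAC-selection logic, cost weighting, INR time series, or
  mixed-model estimation beyond cluster-robust variance.
- The generator does not model clinical events (strokes, bleeds) — the
  underlying trial measured prescribing, not outcomes.
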