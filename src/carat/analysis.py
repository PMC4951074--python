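"""Trial statistics: arm comparisons, univariate screening, forward
stepwise (Wald) logistic regression, and pseudo-R-squared.

The analysis layer mirrors a standard cluster-randomized prescribing
trial: baseline tables compared between arms with Pearson chi-square
(Fisher's exact test when an expected cell is below 5), Welch's
two-sample comparison for continuous variables and rank tests for ordinal
ones; predictors of a binary prescribing outcome screened univariately at
P < 0.10 and entered into a forward stepwise logistic model (Wald entry /
removal tests), reporting odds ratios with 95% confidence intervals,
Cox-Snell and Nagelkerke pseudo-R-squared, and the 0.5-cutoff
classification rate. Inference can be made robust to clustering of
patients within general practitioners via a cluster-robust covariance.
"""

from __future__ import annotations

import enum
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .records import PatientRecord

logger = logging.getLogger(__name__)

ORDINAL_VARIABLES = {"afib_duration"}


class TestKind(str, enum.Enum):
    chi_square = "chi_square"
    fisher_exact = "fisher_exact"
    t_or_anova = "t_or_anova"
    mann_whitney = "mann_whitney"
    kruskal_wallis = "kruskal_wallis"


class DegenerateTestError(ValueError):
    """The variable (or grouping) is constant; no test is possible."""


class InvalidFitError(ValueError):
    """A fitted model's log-likelihood fell below its null's."""


@dataclass
class ArmComparison:
    variable: str
    test: TestKind
    statistic: float
    p_value: float
    note: str = ""


def extract_variable(cohort: Sequence[PatientRecord], name: str) -> list:
    """Pull a (possibly dotted, e.g. ``stroke.hypertension``) field from each record."""
    values = []
    for rec in cohort:
        obj = rec
        for part in name.split("."):
            obj = getattr(obj, part)
        values.append(obj)
    return values


def fisher_exact_p(table: np.ndarray | Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Sums, over the hypergeometric support fixed by the margins, every
    outcome whose probability does not exceed the observed one (with the
    conventional ``1 + 1e-7`` tie tolerance). Computed from log-binomial
    coefficients, vectorized over the support.
    """
    (a, b), (c, d) = np.asarray(table, dtype=int)
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    n = a + b + c + d
    row, col = a + b, a + c
    if n == 0 or row in (0, n) or col in (0, n):
        return 1.0  # degenerate margins: only one table possible
    support = np.arange(max(0, row + col - n), min(row, col) + 1)
    log_pmf = (
        _log_comb(row, support)
        + _log_comb(n - row, col - support)
        - _log_comb(n, col)
    )
    pmf = np.exp(log_pmf)
    observed = pmf[support == a][0]
    return float(min(1.0, pmf[pmf <= observed * (1.0 + 1e-7)].sum()))


def _log_comb(n: float, k: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln

    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _contingency(groups: list, values: list) -> pd.DataFrame:
    return pd.crosstab(pd.Series(groups, dtype=str), pd.Series([str(v) for v in values]))


def compare_arms(
    cohort: Sequence[PatientRecord],
    variable: str,
    by: str = "arm",
    test: Optional[TestKind] = None,
) -> ArmComparison:
    """Compare ``variable`` across the groups defined by ``by``.

    The test is chosen from the variable's type unless forced:
    boolean/categorical -> Pearson chi-square without continuity
    correction, switching to Fisher's exact test on 2x2 tables with any
    expected cell < 5; numeric -> Welch t (two groups) or one-way ANOVA;
    ordinal -> Mann-Whitney U (two groups) or Kruskal-Wallis.
    """
    raw_groups = [str(g.value if hasattr(g, "value") else g) for g in extract_variable(cohort, by)]
    values = extract_variable(cohort, variable)
    group_labels = sorted(set(raw_groups))
    if len(group_labels) < 2:
        raise DegenerateTestError(f"grouping {by!r} has a single level")
    if len(set(map(str, values))) < 2:
        raise DegenerateTestError(f"variable {variable!r} is constant")

    is_ordinal = variable.split(".")[-1] in ORDINAL_VARIABLES
    is_numeric = isinstance(values[0], (int, float)) and not isinstance(values[0], bool)

    if test is None:
        if is_ordinal:
            test = TestKind.mann_whitney if len(group_labels) == 2 else TestKind.kruskal_wallis
        elif is_numeric:
            test = TestKind.t_or_anova
        else:
            test = TestKind.chi_square

    note = ""
    if test in (TestKind.chi_square, TestKind.fisher_exact):
        table = _contingency(raw_groups, values)
        arr = table.to_numpy()
        expected = stats.contingency.expected_freq(arr)
        if test is TestKind.chi_square and arr.shape == (2, 2) and (expected < 5).any():
            test = TestKind.fisher_exact
            note = "expected cell < 5; switched to Fisher exact"
        if test is TestKind.fisher_exact:
            if arr.shape != (2, 2):
                raise ValueError("Fisher exact supported for 2x2 tables only")
            with np.errstate(divide="ignore", invalid="ignore"):
                odds = arr[0, 0] * arr[1, 1] / (arr[0, 1] * arr[1, 0])
            return ArmComparison(variable, test, float(odds), fisher_exact_p(arr), note)
        stat, p, _, _ = stats.chi2_contingency(arr, correction=False)
        return ArmComparison(variable, test, float(stat), float(p), note)

    if is_ordinal:
        order = {v: i for i, v in enumerate(type(values[0]))}
        coded = np.array([order[v] for v in values], dtype=float)
    else:
        coded = np.asarray(values, dtype=float)
    samples = [coded[np.asarray(raw_groups) == g] for g in group_labels]

    if test is TestKind.mann_whitney:
        stat, p = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
    elif test is TestKind.kruskal_wallis:
        stat, p = stats.kruskal(*samples)
    elif len(samples) == 2:
        stat, p = stats.ttest_ind(samples[0], samples[1], equal_var=False)
        note = note or "Welch two-sample t"
    else:
        stat, p = stats.f_oneway(*samples)
    return ArmComparison(variable, test, float(stat), float(p), note)


def compare_means_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    equal_var: bool = False,
) -> tuple[float, float]:
    """Two-sample t from printed summary statistics; returns (t, p)."""
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Logistic modelling
# ---------------------------------------------------------------------------

_SEPARATION_COEF = 15.0  # |log-odds| beyond this is treated as (quasi-)separation


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    """Fit a logistic regression with intercept; None on failure."""
    Xc = sm.add_constant(X.astype(float), has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200, warn_convergence=False)
        if not np.all(np.isfinite(res.params)):
            return None
        return res
    except Exception as exc:  # separation, singular matrix, ...
        logger.debug("logit fit failed for %s: %s", list(X.columns), exc)
        return None


@dataclass
class ScreenResult:
    selected: list[str]
    p_values: dict[str, float]
    separation_flagged: list[str] = field(default_factory=list)
    excluded_constant: list[str] = field(default_factory=list)


def univariate_screen(
    outcome: Sequence[int], covariates: pd.DataFrame, alpha: float = 0.10
) -> ScreenResult:
    """Single-predictor logistic screen; keep covariates with Wald p < alpha.

    Constant covariates are excluded with a warning; covariates producing
    (quasi-)separation are flagged and retained.
    """
    y = np.asarray(outcome, dtype=float)
    if len(np.unique(y)) < 2:
        raise DegenerateTestError("outcome is constant")
    result = ScreenResult(selected=[], p_values={})
    for name in covariates.columns:
        x = covariates[[name]]
        if x[name].nunique() < 2:
            result.excluded_constant.append(name)
            logger.warning("covariate %r is constant; excluded from screen", name)
            continue
        res = _fit_logit(y, x)
        if res is None or abs(res.params[name]) > _SEPARATION_COEF:
            result.separation_flagged.append(name)
            result.selected.append(name)
            result.p_values[name] = math.nan
            logger.warning("covariate %r shows separation; retained with warning", name)
            continue
        p = float(res.pvalues[name])
        result.p_values[name] = p
        if p < alpha:
            result.selected.append(name)
    return result


@dataclass
class ModelTerm:
    name: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class LogisticModelResult:
    outcome: str
    terms: list[ModelTerm]
    classification_rate: float
    r2_cox_snell: float
    r2_nagelkerke: float
    cluster_adjusted: bool
    n: int
    llf: float
    llnull: float
    skipped: list[str] = field(default_factory=list)

    def term(self, name: str) -> ModelTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


def pseudo_r2_from_ll(ll0: float, ll1: float, n: int) -> tuple[float, float]:
    """Cox-Snell and Nagelkerke pseudo-R2 from null/model log-likelihoods."""
    if ll1 < ll0 - 1e-8:
        raise InvalidFitError(f"model log-likelihood {ll1} below null {ll0}")
    cox_snell = 1.0 - math.exp(2.0 * (ll0 - ll1) / n)
    max_cs = 1.0 - math.exp(2.0 * ll0 / n)
    nagelkerke = cox_snell / max_cs if max_cs > 0 else 0.0
    return cox_snell, nagelkerke


def pseudo_r2(fit) -> tuple[float, float]:
    """Pseudo-R2 pair from a fitted statsmodels logit result."""
    return pseudo_r2_from_ll(float(fit.llnull), float(fit.llf), int(fit.nobs))


def classification_rate(fit, y: np.ndarray, cutoff: float = 0.5) -> float:
    pred = (np.asarray(fit.predict()) >= cutoff).astype(float)
    return float(np.mean(pred == np.asarray(y, dtype=float)))


def forward_stepwise_wald(
    outcome: Sequence[int],
    candidates: pd.DataFrame,
    entry_p: float = 0.05,
    removal_p: float = 0.10,
    groups: Optional[Sequence] = None,
    outcome_name: str = "outcome",
) -> LogisticModelResult:
    """Forward stepwise logistic regression with Wald entry/removal tests.

    Starting from the intercept-only model, the candidate with the
    smallest Wald p-value below ``entry_p`` is added; after each entry,
    included terms whose Wald p exceeds ``removal_p`` are removed.
    Candidate order is immaterial: ties in p are broken by covariate name.
    Candidates whose fit fails (separation, singularity) are skipped and
    recorded. When ``groups`` is given, the final model's standard errors
    and CIs use a cluster-robust covariance over those groups.
    """
    y = np.asarray(outcome, dtype=float)
    names = sorted(candidates.columns)
    included: list[str] = []
    skipped: list[str] = []
    seen_states: set[frozenset] = set()

    while True:
        state = frozenset(included)
        if state in seen_states:
            break  # guards against entry/removal cycles
        seen_states.add(state)

        best_name, best_p = None, None
        for name in names:
            if name in included or name in skipped:
                continue
            res = _fit_logit(y, candidates[included + [name]])
            if res is None or abs(res.params[name]) > _SEPARATION_COEF:
                skipped.append(name)
                logger.warning("candidate %r skipped (non-convergence/separation)", name)
                continue
            p = float(res.pvalues[name])
            if best_p is None or p < best_p:
                best_name, best_p = name, p
        if best_name is None or best_p >= entry_p:
            break
        included.append(best_name)

        while included:
            res = _fit_logit(y, candidates[included])
            if res is None:
                skipped.append(included.pop())
                continue
            worst = max(included, key=lambda t: float(res.pvalues[t]))
            if float(res.pvalues[worst]) > removal_p:
                included.remove(worst)
            else:
                break

    Xc = sm.add_constant(candidates[included].astype(float), has_constant="add")
    plain = sm.Logit(y, Xc).fit(disp=0, maxiter=200, warn_convergence=False)
    cluster_adjusted = False
    final = plain
    if groups is not None and included:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                final = sm.Logit(y, Xc).fit(
                    disp=0,
                    maxiter=200,
                    warn_convergence=False,
                    cov_type="cluster",
                    cov_kwds={"groups": np.asarray(groups)},
                )
            cluster_adjusted = True
        except Exception as exc:  # fall back to the plain fit
            logger.warning("cluster-robust covariance failed (%s); plain fit reported", exc)

    ci = final.conf_int()
    terms = [
        ModelTerm(
            name=t,
            odds_ratio=float(np.exp(final.params[t])),
            ci_low=float(np.exp(ci.loc[t, 0])),
            ci_high=float(np.exp(ci.loc[t, 1])),
            p_value=float(final.pvalues[t]),
        )
        for t in included
    ]
    cs, nk = pseudo_r2(plain)
    return LogisticModelResult(
        outcome=outcome_name,
        terms=terms,
        classification_rate=classification_rate(plain, y),
        r2_cox_snell=cs,
        r2_nagelkerke=nk,
        cluster_adjusted=cluster_adjusted,
        n=int(plain.nobs),
        llf=float(plain.llf),
        llnull=float(plain.llnull),
        skipped=skipped,
    )
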