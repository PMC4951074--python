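"""Change taxonomy, agreement statistics, Fleiss kappa, therapy summaries."""

from collections import Counter
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from carat.changes import (
    AgreementRecord,
    ChangeClass,
    DegenerateMarginsError,
    UnrankableRegimenError,
    build_rating_table,
    classify_change,
    fleiss_kappa,
    percent_agreement,
    summarize_agreement,
    tabulate_changes,
    tally_reasons,
    therapy_distribution,
)
from carat.records import Regimen, TherapyClass, therapy_class

RANKED = [r for r in Regimen if r is not Regimen.other]
RANK = {TherapyClass.none: 0, TherapyClass.antiplatelet: 1, TherapyClass.anticoagulant: 2}


class TestClassifyChange:
    @pytest.mark.parametrize(
        "baseline,target,dose,expected",
        [
            ("none", "warfarin", False, ChangeClass.upgrade),
            ("aspirin_only", "warfarin", False, ChangeClass.upgrade),
            ("aspirin_only", "dabigatran", False, ChangeClass.upgrade),
            ("warfarin_plus_antiplatelet", "warfarin", False, ChangeClass.side_step),
            ("warfarin", "dabigatran", False, ChangeClass.side_step),
            ("dabigatran", "aspirin_only", False, ChangeClass.downgrade),
            ("warfarin", "aspirin_only", False, ChangeClass.downgrade),
            ("aspirin_only", "none", False, ChangeClass.downgrade),
            ("warfarin", "warfarin", False, ChangeClass.no_change),
            ("warfarin", "warfarin", True, ChangeClass.dose_adjust),
        ],
    )
    def test_examples(self, baseline, target, dose, expected):
        assert classify_change(baseline, target, dose) is expected

    def test_partition_over_all_ranked_pairs(self):
        """Exactly one class per transition; class agrees with the rank ordering."""
        for b, t in product(RANKED, RANKED):
            c = classify_change(b, t)
            rb, rt = RANK[therapy_class(b)], RANK[therapy_class(t)]
            if b == t:
                assert c is ChangeClass.no_change
            elif rt > rb:
                assert c is ChangeClass.upgrade
            elif rt < rb:
                assert c is ChangeClass.downgrade
            else:
                assert c is ChangeClass.side_step

    def test_antisymmetry(self):
        for b, t in product(RANKED, RANKED):
            if classify_change(b, t) is ChangeClass.upgrade:
                assert classify_change(t, b) is ChangeClass.downgrade

    def test_other_regimen_unrankable_without_configured_rank(self):
        with pytest.raises(UnrankableRegimenError):
            classify_change("warfarin", "other")
        assert classify_change("warfarin", "other", other_rank=2) is ChangeClass.side_step


class TestTabulateChanges:
    def test_trial_counts_reproduce_printed_percentages(self):
        transitions = (
            [("aspirin_only", "warfarin", False)] * 12
            + [("warfarin_plus_antiplatelet", "warfarin", False)] * 35
            + [("warfarin", "aspirin_only", False)] * 28
        )
        tab = tabulate_changes(transitions)
        assert tab.n_changes == 75
        assert tab.percent_of_changes == {
            ChangeClass.upgrade: 16.0,
            ChangeClass.side_step: 46.7,
            ChangeClass.downgrade: 37.3,
        }

    def test_single_upgrade_is_100_percent(self):
        tab = tabulate_changes([("none", "aspirin_only", False)])
        assert tab.percent_of_changes[ChangeClass.upgrade] == 100.0

    def test_counts_conserve_total(self):
        transitions = [("warfarin", "warfarin", False)] * 5 + [
            ("none", "warfarin", False),
            ("warfarin", "warfarin", True),
        ]
        tab = tabulate_changes(transitions)
        assert sum(tab.counts.values()) == tab.n == 7

    def test_zero_change_denominator_is_undefined(self):
        tab = tabulate_changes([("warfarin", "warfarin", False)] * 75)
        assert tab.n_changes == 0
        assert tab.percent_of_changes is None

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            tabulate_changes([])


class TestAgreement:
    def test_all_agree(self):
        pairs = [AgreementRecord.from_pair("warfarin", "warfarin")] * 4
        assert percent_agreement(pairs) == 1.0

    def test_one_of_four_disagrees(self):
        pairs = [AgreementRecord.from_pair("warfarin", "warfarin")] * 3 + [
            AgreementRecord.from_pair("warfarin", "dabigatran")
        ]
        assert percent_agreement(pairs) == 0.75

    def test_155_of_206_matches_printed_share(self):
        pairs = [AgreementRecord.from_pair("warfarin", "warfarin")] * 155 + [
            AgreementRecord.from_pair("warfarin", "dabigatran")
        ] * 51
        assert round(percent_agreement(pairs), 3) == 0.752

    def test_class_agreement_coarser_than_regimen(self):
        p = AgreementRecord.from_pair("warfarin", "dabigatran")
        assert not p.agree_overall and p.agree_class and not p.agree_agent
        q = AgreementRecord.from_pair("warfarin", "warfarin_plus_antiplatelet")
        assert q.agree_agent and q.agree_class and not q.agree_overall

    def test_agent_agreement_implies_class_agreement_enforced(self):
        with pytest.raises(Exception):
            AgreementRecord(
                carat_therapy=Regimen.warfarin,
                gp_final_therapy=Regimen.aspirin_only,
                agree_overall=False,
                agree_class=False,
                agree_agent=True,
            )

    def test_reason_tally_counts_disagreements_only(self):
        pairs = [
            AgreementRecord.from_pair("warfarin", "warfarin"),
            AgreementRecord.from_pair("warfarin", "dabigatran", "patient_refusal"),
            AgreementRecord.from_pair("warfarin", "aspirin_only", "patient_refusal"),
            AgreementRecord.from_pair("aspirin_only", "none", "cardiologist"),
        ]
        assert tally_reasons(pairs) == {"patient_refusal": 2, "cardiologist": 1}
        assert sum(tally_reasons(pairs).values()) == 3

    def test_no_disagreements_empty_tally(self):
        assert tally_reasons([AgreementRecord.from_pair("none", "none")]) == {}


def brute_force_two_rater_kappa(a: list, b: list) -> float:
    """Direct counting of observed and pooled-marginal chance agreement."""
    n = len(a)
    p_obs = sum(x == y for x, y in zip(a, b)) / n
    pooled = Counter(list(a) + list(b))
    p_exp = sum((c / (2 * n)) ** 2 for c in pooled.values())
    return (p_obs - p_exp) / (1 - p_exp)


class TestFleissKappa:
    def test_perfect_agreement_with_both_categories_used(self):
        table = np.array([[2, 0]] * 5 + [[0, 2]] * 5)
        assert fleiss_kappa(table) == pytest.approx(1.0)

    def test_hand_computed_toy_table(self):
        # 4 subjects, 2 raters, 3 agreements; P_obs = 3/4, pooled
        # marginals (5/8, 3/8) so P_exp = 25/64 + 9/64 = 17/32;
        # kappa = (3/4 - 17/32) / (1 - 17/32) = 7/15.
        table = [[2, 0], [0, 2], [2, 0], [1, 1]]
        assert fleiss_kappa(table) == pytest.approx(7 / 15, abs=1e-12)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.data())
    def test_matches_brute_force_two_rater_oracle(self, data):
        n = data.draw(st.integers(4, 50))
        k = data.draw(st.integers(2, 4))
        a = data.draw(st.lists(st.integers(0, k - 1), min_size=n, max_size=n))
        b = data.draw(st.lists(st.integers(0, k - 1), min_size=n, max_size=n))
        pooled = set(a) | set(b)
        if len(pooled) < 2:
            return  # degenerate marginals are tested separately
        table, _ = build_rating_table(a, b)
        assert fleiss_kappa(table) == pytest.approx(
            brute_force_two_rater_kappa(a, b), abs=1e-10
        )

    def test_matches_statsmodels_on_random_tables(self):
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss

        rng = np.random.default_rng(0)
        for _ in range(50):
            raters, cats, subjects = 3, 3, 20
            table = rng.multinomial(raters, [1 / cats] * cats, size=subjects)
            assert fleiss_kappa(table) == pytest.approx(float(sm_fleiss(table)), abs=1e-10)

    def test_independent_random_ratings_give_near_zero(self):
        rng = np.random.default_rng(42)
        a, b = rng.integers(0, 2, 5000), rng.integers(0, 2, 5000)
        table, _ = build_rating_table(a.tolist(), b.tolist())
        assert abs(fleiss_kappa(table)) < 0.05

    def test_degenerate_marginals_signalled(self):
        with pytest.raises(DegenerateMarginsError):
            fleiss_kappa(np.array([[2, 0], [2, 0]]))

    def test_unequal_rater_counts_rejected(self):
        with pytest.raises(ValueError):
            fleiss_kappa(np.array([[2, 0], [2, 1]]))


class TestSummaries:
    def test_summarize_agreement_reports_both_levels(self):
        pairs = [AgreementRecord.from_pair("warfarin", "warfarin")] * 6 + [
            AgreementRecord.from_pair("warfarin", "dabigatran", "familiarization_program")
        ] * 2
        res = summarize_agreement(pairs)
        assert res.percent_agreement == 0.75
        assert res.percent_class_agreement == 1.0
        assert res.reason_tally == {"familiarization_program": 2}
        assert res.n == 8

    def test_therapy_distribution_percentages(self):
        regimens = ["warfarin"] * 8 + ["aspirin_only"] * 1 + ["none"] * 1
        d = therapy_distribution(regimens)
        assert d.pct_any_antithrombotic == 90.0
        assert d.pct_anticoagulant == 80.0
        assert d.pct_agent_among_treated("warfarin") == pytest.approx(88.9)
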