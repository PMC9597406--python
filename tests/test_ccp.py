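"""Transition identification, the CCP rule and group statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from gaitcosts.ccp import (
    ChoiceSequence,
    ccp_from_percent,
    ccp_summary,
    compare_conditions,
    evaluate_ccp,
    identify_transitions,
)
from gaitcosts.costs import TrialCosts
from gaitcosts.datasets import table1_ccp_results
from gaitcosts.exceptions import ConfigurationError, DataError


def seq(mapping):
    return ChoiceSequence(participant_id="X", choices=mapping)


class TestTransitions:
    def test_single_transition_at_24(self):
        tr = identify_transitions(
            seq({0: "incline", 6: "incline", 12: "incline", 18: "incline", 24: "crouch"})
        )
        assert tr.pre_transition_grade == 18
        assert tr.post_transition_grade == 24
        assert tr.monotone

    def test_crouch_everywhere(self):
        tr = identify_transitions(seq({g: "crouch" for g in (0, 6, 12, 18, 24)}))
        assert tr.pre_transition_grade is None
        assert tr.post_transition_grade == 0
        assert tr.monotone

    def test_incline_everywhere(self):
        tr = identify_transitions(seq({g: "incline" for g in (0, 6, 12, 18, 24)}))
        assert tr.pre_transition_grade == 24
        assert tr.post_transition_grade is None
        assert tr.monotone

    def test_non_monotone_sequence(self):
        tr = identify_transitions(
            seq({0: "incline", 6: "crouch", 12: "incline", 18: "crouch", 24: "crouch"})
        )
        assert tr.pre_transition_grade == 12
        assert tr.post_transition_grade == 6
        assert not tr.monotone

    def test_missing_grade_rejected(self):
        with pytest.raises(ConfigurationError):
            identify_transitions(seq({0: "incline"}))


def costs_of(met, a2, amax=1.0, avol=1.0, pid="p", cond=""):
    return TrialCosts(
        c_met_p=met, c_a2=a2, c_a_max=amax, c_a_vol=avol,
        condition=cond, participant_id=pid,
    )


class TestCcpRule:
    def test_worked_example_participant_1(self):
        crouch = {"c_met_p": 172.5, "c_a2": 566.0, "c_a_max": 292.2, "c_a_vol": 167.1}
        incline = {"c_met_p": 189.5, "c_a2": 290.8, "c_a_max": 196.8, "c_a_vol": 125.7}
        r = ccp_from_percent("1", crouch, incline)
        assert r.ccp_a2 is True
        assert r.advantage_a2 == pytest.approx(100 * (566.0 - 290.8) / 290.8)
        assert round(r.advantage_a2, 1) == 94.6
        assert r.penalty_met == pytest.approx(100 * (189.5 - 172.5) / 189.5)
        assert round(r.penalty_met, 1) == 9.0

    def test_worked_example_participant_6_fails_metabolic_condition(self):
        crouch = {"c_met_p": 204.9, "c_a2": 1409.4, "c_a_max": 747.6, "c_a_vol": 239.7}
        incline = {"c_met_p": 202.5, "c_a2": 454.2, "c_a_max": 368.4, "c_a_vol": 154.4}
        r = ccp_from_percent("6", crouch, incline)
        assert r.ccp_a2 is False and r.ccp_a_max is False and r.ccp_a_vol is False

    def test_exact_ties_yield_no_ccp(self):
        vals = {"c_met_p": 150.0, "c_a2": 300.0, "c_a_max": 200.0, "c_a_vol": 120.0}
        r = ccp_from_percent("t", vals, dict(vals))
        assert r.ccp_a2 is False and r.ccp_a_max is False and r.ccp_a_vol is False

    def test_missing_activation_gives_none_flags(self):
        crouch = {"c_met_p": 170.9, "c_a2": float("nan")}
        incline = {"c_met_p": 200.6, "c_a2": float("nan")}
        r = ccp_from_percent("5", crouch, incline)
        assert r.ccp_a2 is None
        assert not r.has_activation
        assert np.isnan(r.advantage_a2)

    @given(k=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, k):
        crouch = costs_of(6.0, 5.0, 3.5, 2.0)
        incline = costs_of(8.0, 3.0, 2.5, 1.6)
        base = costs_of(4.0, 1.01, 1.02, 1.0)
        scale = lambda c: costs_of(
            k * c.c_met_p, k * c.c_a2, k * c.c_a_max, k * c.c_a_vol
        )
        r1 = evaluate_ccp(crouch, incline, base)
        r2 = evaluate_ccp(scale(crouch), scale(incline), scale(base))
        assert r1.ccp_a2 == r2.ccp_a2
        assert r1.advantage_a2 == pytest.approx(r2.advantage_a2, rel=1e-9)
        assert r1.penalty_met == pytest.approx(r2.penalty_met, rel=1e-9)

    def test_antisymmetry_of_orientation(self):
        crouch = costs_of(6.0, 5.0, 3.5, 2.0)
        incline = costs_of(8.0, 3.0, 2.5, 1.6)
        base = costs_of(4.0, 1.0, 1.0, 1.0)
        fwd = evaluate_ccp(crouch, incline, base)
        rev = evaluate_ccp(incline, crouch, base)
        # CCP can never hold in both orientations
        assert not (fwd.ccp_a2 and rev.ccp_a2)
        assert np.sign(fwd.advantage_a2) == -np.sign(rev.advantage_a2)
        assert np.sign(fwd.penalty_met) == -np.sign(rev.penalty_met)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(DataError):
            evaluate_ccp(
                costs_of(6.0, 5.0), costs_of(8.0, 3.0), costs_of(0.0, 1.0)
            )


class TestTable1Reproduction:
    def test_full_ccp_column(self):
        results = table1_ccp_results()
        flags = {r.participant_id: r.ccp_a2 for r in results}
        assert flags == {
            "1": True, "2": True, "3": True, "4": True, "5": None,
            "6": False, "7": None, "8": True, "9": True, "10": True,
        }
        # same pattern for the secondary pairings
        for attr in ("ccp_a_max", "ccp_a_vol"):
            assert {r.participant_id: getattr(r, attr) for r in results} == flags

    def test_summary_single_participant_collapses(self):
        one = [r for r in table1_ccp_results() if r.participant_id == "1"]
        s = ccp_summary(one, restrict_to_ccp=True)
        assert s.loc["advantage_a2", "mean"] == s.loc["advantage_a2", "min"]
        assert s.loc["advantage_a2", "n"] == 1

    def test_empty_selection_errors(self):
        no_ccp = [r for r in table1_ccp_results() if r.participant_id == "6"]
        with pytest.raises(DataError):
            ccp_summary(no_ccp, restrict_to_ccp=True)


class TestCompareConditions:
    def test_identical_conditions_not_significant(self):
        df = pd.DataFrame(
            {"crouch": [5.0] * 6, "pre": [5.0] * 6, "post": [5.0] * 6}
        )
        rep = compare_conditions(df)
        assert not rep.significant
        assert len(rep.posthoc) == 0

    def test_large_effect_all_pairwise_significant(self):
        rng = np.random.default_rng(42)
        n = 10
        base = rng.normal(8.0, 0.05, n)
        df = pd.DataFrame(
            {"crouch": base, "pre": base + 2.0 + rng.normal(0, 0.05, n),
             "post": base + 4.0 + rng.normal(0, 0.05, n)}
        )
        rep = compare_conditions(df, posthoc_alpha=0.017)
        assert rep.significant
        assert len(rep.posthoc) == 3
        assert rep.posthoc["significant"].all()
        assert (rep.posthoc["p"] < 0.017).all()

    def test_skewed_data_takes_nonparametric_branch(self):
        rng = np.random.default_rng(7)
        n = 12
        skew = rng.lognormal(0.0, 1.8, n)  # heavy right tail fails the Shapiro screen
        df = pd.DataFrame(
            {"crouch": skew, "pre": skew * 3.0, "post": skew * 9.0}
        )
        rep = compare_conditions(df)
        assert rep.branch == "nonparametric"
        assert rep.omnibus_test == "Friedman"

    def test_incomplete_triples_listed(self):
        df = pd.DataFrame(
            {"crouch": [1.0, 2.0, np.nan], "pre": [1.0, 2.0, 3.0], "post": [1.0, 2.0, 3.0]},
            index=["a", "b", "c"],
        )
        with pytest.raises(DataError, match="c"):
            compare_conditions(df)

    def test_too_few_triples(self):
        df = pd.DataFrame({"crouch": [1.0, 2.0], "pre": [2.0, 3.0], "post": [3.0, 4.0]})
        with pytest.raises(DataError):
            compare_conditions(df)
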