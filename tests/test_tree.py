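"""Decision-tree evaluation: outcome distributions, pathway values, arm means."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from antescreen.parameters import STRATEGIES, default_parameters
from antescreen.tree import (
    evaluate_all,
    evaluate_arm,
    outcome_distribution_single,
    outcome_distribution_two_stage,
    pathway_values,
    strategy_outcome_distribution,
)

probs = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


class TestOutcomeDistributions:
    def test_single_stage_from_unaided_detection_values(self):
        d = outcome_distribution_single(0.0438, 0.6667, 0.8855)
        assert d.p_tp == pytest.approx(0.0292, abs=1e-4)
        assert d.p_fp == pytest.approx(0.0146, abs=1e-4)
        assert d.p_tn == pytest.approx(0.8467, abs=1e-4)
        assert d.p_fn == pytest.approx(0.1095, abs=1e-4)

    def test_perfect_test(self):
        d = outcome_distribution_single(0.2, 1.0, 1.0)
        assert d.as_tuple() == pytest.approx((0.2, 0.0, 0.8, 0.0))

    def test_never_screens_positive(self):
        d = outcome_distribution_single(0.0, 0.7, 0.9)
        assert d.as_tuple() == pytest.approx((0.0, 0.0, 0.9, 0.1))

    def test_out_of_range_input_rejected(self):
        with pytest.raises(ValueError):
            outcome_distribution_single(1.2, 0.5, 0.5)

    def test_two_stage_default_block(self, params):
        d = outcome_distribution_two_stage(params.accuracy["whooley_epds"])
        assert d.p_tp == pytest.approx(0.0276, abs=1e-4)
        assert d.p_fp == pytest.approx(0.0092, abs=1e-4)
        assert d.p_tn == pytest.approx(0.8902, abs=1e-4)
        assert d.p_fn == pytest.approx(0.0730, abs=1e-4)
        assert sum(d.as_tuple()) == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_second_stage_reduces_to_single(self):
        p = default_parameters()
        acc = p.accuracy["whooley_epds"]
        acc.p_stage2_positive_given_stage1_positive.mean = 1.0
        single = outcome_distribution_single(
            acc.p_stage1_positive.mean,
            acc.p_tp_given_both_positive.mean,
            acc.p_tn_given_stage1_negative.mean,
        )
        two = outcome_distribution_two_stage(acc)
        assert two.as_tuple() == pytest.approx(single.as_tuple())

    def test_stage1_never_positive(self):
        p = default_parameters()
        acc = p.accuracy["whooley_epds"]
        acc.p_stage1_positive.mean = 0.0
        d = outcome_distribution_two_stage(acc)
        s = acc.p_tn_given_stage1_negative.mean
        assert d.as_tuple() == pytest.approx((0.0, 0.0, s, 1 - s))

    def test_two_stage_requires_two_stage_fields(self, params):
        with pytest.raises(ValueError):
            outcome_distribution_two_stage(params.accuracy["whooley"])

    @given(p=probs, tp=probs, tn=probs)
    @settings(max_examples=200, deadline=None)
    def test_probabilities_partition_unity(self, p, tp, tn):
        d = outcome_distribution_single(p, tp, tn)
        assert sum(d.as_tuple()) == pytest.approx(1.0, abs=1e-9)
        assert all(-1e-12 <= x <= 1 + 1e-12 for x in d.as_tuple())


class TestPathwayValues:
    def test_expected_values_from_treatment_pathway(self, params):
        pv = pathway_values(params)
        # Hand expectations over the tree, frozen before implementation.
        assert pv.qaly_tp == pytest.approx(0.6298, abs=5e-4)
        assert pv.qaly_fn == pytest.approx(0.6198, abs=5e-4)
        assert pv.qaly_fp == pv.qaly_tn == params.qalys["nondepressed_to_nondepressed"].value
        assert pv.cost_tp == pytest.approx(3076.2, abs=0.5)
        assert pv.cost_fp == pytest.approx(1929.7, abs=0.5)
        assert pv.cost_tn == 1680.0
        assert pv.cost_fn == pytest.approx(1971.3, abs=0.5)

    def test_ordering_invariants(self, params):
        pv = pathway_values(params)
        assert pv.qaly_fn <= pv.qaly_tp
        assert pv.cost_tn <= pv.cost_fp

    def test_universal_spontaneous_recovery(self):
        p = default_parameters()
        p.treatment.p_spontaneous.mean = 1.0
        pv = pathway_values(p)
        assert pv.qaly_fn == p.qalys["depressed_to_nondepressed"].value
        assert pv.cost_fn == p.costs.other_care_nondepressed.mean


class TestArmEvaluation:
    @pytest.mark.parametrize(
        "strategy, qaly, cost",
        [
            ("no_screen", 0.7255, 1765.0),
            ("whooley", 0.7302, 1772.0),
            ("epds", 0.7304, 1799.0),
            ("whooley_epds", 0.7301, 1748.0),
        ],
    )
    def test_reproduces_published_arm_means(self, params, strategy, qaly, cost):
        arm = evaluate_arm(strategy, params)
        assert arm.mean_qaly == pytest.approx(qaly, abs=5e-4)
        assert arm.mean_cost == pytest.approx(cost, abs=2.0)

    def test_arm_ordering_matches_published_ranking(self, base_arms):
        by = {a.strategy: a for a in base_arms}
        assert [a.strategy for a in base_arms] == list(STRATEGIES)
        assert max(base_arms, key=lambda a: a.mean_qaly).strategy == "epds"
        assert max(base_arms, key=lambda a: a.mean_cost).strategy == "epds"
        assert min(base_arms, key=lambda a: a.mean_cost).strategy == "whooley_epds"
        assert by["no_screen"].mean_qaly == min(a.mean_qaly for a in base_arms)

    def test_unknown_strategy_rejected(self, params):
        with pytest.raises(KeyError):
            evaluate_arm("phq9", params)

    def test_degenerate_all_negative_arm(self):
        p = default_parameters()
        acc = p.accuracy["epds"]
        acc.p_positive.mean = 0.0
        acc.p_tn_given_negative.mean = 1.0
        arm = evaluate_arm("epds", p)
        assert arm.mean_qaly == pytest.approx(p.qalys["nondepressed_to_nondepressed"].value)
        assert arm.mean_cost == pytest.approx(
            p.costs.screen_cost["epds"].mean + p.costs.other_care_nondepressed.mean
        )

    def test_identical_accuracy_differs_only_by_screening_cost(self):
        p = default_parameters()
        for s in STRATEGIES:
            if s == "whooley_epds":
                continue
            acc = p.accuracy[s]
            acc.p_positive.mean = 0.1
            acc.p_tp_given_positive.mean = 0.5
            acc.p_tn_given_negative.mean = 0.93
        arms = {a.strategy: a for a in evaluate_all(p)}
        for s in ("epds", "no_screen"):
            assert arms[s].mean_qaly == pytest.approx(arms["whooley"].mean_qaly)
            assert arms[s].mean_cost - arms["whooley"].mean_cost == pytest.approx(
                p.costs.screen_cost[s].mean - p.costs.screen_cost["whooley"].mean
            )

    def test_mean_qaly_and_cost_bounds(self, params, base_arms):
        pv = pathway_values(params)
        q_values = [params.qalys[r].value for r in params.qalys]
        for arm in base_arms:
            assert min(q_values) <= arm.mean_qaly <= max(q_values)
            screen = params.costs.screen_cost[arm.strategy].mean
            assert screen + pv.cost_tn <= arm.mean_cost <= screen + pv.cost_tp

    @given(delta=st.floats(min_value=0.0, max_value=0.06))
    @settings(max_examples=50, deadline=None)
    def test_fewer_false_negatives_raises_qalys_and_lowers_cost(self, delta):
        # Converting false negatives to true negatives (higher negative
        # predictive value) gains QALYs and saves other-care costs, because
        # at the defaults the well state beats the false-negative pathway
        # on both axes.
        p = default_parameters()
        base = evaluate_arm("whooley", p)
        p.accuracy["whooley"].p_tn_given_negative.mean = min(
            1.0, p.accuracy["whooley"].p_tn_given_negative.mean + delta
        )
        arm = evaluate_arm("whooley", p)
        assert arm.mean_qaly >= base.mean_qaly - 1e-12
        assert arm.mean_cost <= base.mean_cost + 1e-9

    @given(delta=st.floats(min_value=0.0, max_value=0.4))
    @settings(max_examples=50, deadline=None)
    def test_richer_case_mix_among_positives_raises_cost(self, delta):
        # More true positives per positive screen means more full courses
        # of treatment, so arm cost is non-decreasing in the positive
        # predictive value.
        p = default_parameters()
        base = evaluate_arm("whooley", p)
        p.accuracy["whooley"].p_tp_given_positive.mean = min(
            1.0, p.accuracy["whooley"].p_tp_given_positive.mean + delta
        )
        assert evaluate_arm("whooley", p).mean_cost >= base.mean_cost - 1e-9

    def test_vectorised_evaluation_matches_scalar(self, params):
        # Array-valued parameters evaluate elementwise, enabling the PSA path.
        p = default_parameters()
        p.accuracy["whooley"].p_positive.mean = np.array([0.0909, 0.2])
        d = strategy_outcome_distribution("whooley", p)
        scalar = outcome_distribution_single(0.2, 0.4530, 0.9341)
        assert d.p_tp[1] == pytest.approx(scalar.p_tp)
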