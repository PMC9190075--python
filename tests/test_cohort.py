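"""Synthetic cohorts: simulation, parameter recovery and the microsim oracle."""

import numpy as np
import pytest

from antescreen.cohort import (
    CohortConfig,
    EstimationError,
    estimate_strategy_params,
    expected_strategy_accuracy,
    implied_screen_characteristics,
    implied_two_stage_characteristics,
    microsimulate_arm,
    simulate_cohort,
    strategy_cohort_config,
    survey_cohort_config,
)
from antescreen.parameters import STRATEGIES, default_parameters
from antescreen.tree import evaluate_arm


@pytest.fixture(scope="module")
def survey_cfg(params):
    return survey_cohort_config(params, n_women=200_000, seed=3)


@pytest.fixture(scope="module")
def survey_cohort(survey_cfg):
    return simulate_cohort(survey_cfg)


def perfect_config(n=2000, seed=0):
    return CohortConfig(
        n_women=n,
        prevalence=0.2,
        whooley_sensitivity=1.0,
        whooley_specificity=1.0,
        epds_sensitivity_given_whooley_pos=1.0,
        epds_specificity_given_whooley_pos=1.0,
        epds_sensitivity_given_whooley_neg=1.0,
        epds_specificity_given_whooley_neg=1.0,
        no_screen_sensitivity=1.0,
        no_screen_specificity=1.0,
        seed=seed,
    )


class TestConfigDerivation:
    def test_survey_config_matches_source_accuracy(self, survey_cfg):
        # The survey blocks imply a prevalence near the reported ~10-11%
        # and midwife-unaided detection near sensitivity 21%, specificity 98%.
        assert survey_cfg.prevalence == pytest.approx(0.1006, abs=0.001)
        assert survey_cfg.no_screen_sensitivity == pytest.approx(0.21, abs=0.01)
        assert survey_cfg.no_screen_specificity == pytest.approx(0.98, abs=0.005)
        survey_cfg.validate()

    def test_implied_characteristics_invert_bayes(self, params):
        prev, sens, spec = implied_screen_characteristics(params.accuracy["whooley"])
        p_pos = prev * sens + (1 - prev) * (1 - spec)
        assert p_pos == pytest.approx(0.0909, abs=1e-6)
        assert prev * sens / p_pos == pytest.approx(0.4530, abs=1e-6)

    def test_two_stage_implied_prevalence_consistent(self, params):
        two = implied_two_stage_characteristics(params.accuracy["whooley_epds"])
        prev_epds, _, _ = implied_screen_characteristics(params.accuracy["epds"])
        # The survey blocks describe one population: prevalences agree closely.
        assert two["prevalence"] == pytest.approx(prev_epds, abs=1e-4)

    def test_expected_accuracy_reproduces_block(self, params):
        # Strategy-matched configs must invert back to the accuracy block.
        for strategy in STRATEGIES:
            cfg = strategy_cohort_config(params, strategy, n_women=100)
            acc = expected_strategy_accuracy(cfg, strategy)
            for got, want in zip(
                acc.probability_params(), params.accuracy[strategy].probability_params()
            ):
                assert got.mean == pytest.approx(want.mean, abs=1e-9), strategy


class TestSimulation:
    def test_seed_reproducibility(self, survey_cfg):
        a = simulate_cohort(survey_cfg)
        b = simulate_cohort(survey_cfg)
        assert a.equals(b)

    def test_perfect_tests_equal_truth(self):
        cohort = simulate_cohort(perfect_config())
        assert (cohort.whooley_positive == cohort.true_depressed).all()
        assert (cohort.epds_positive == cohort.true_depressed).all()
        assert (cohort.no_screen_positive == cohort.true_depressed).all()

    def test_prevalence_within_binomial_error(self, survey_cfg, survey_cohort):
        p = survey_cfg.prevalence
        se = np.sqrt(p * (1 - p) / survey_cfg.n_women)
        assert abs(survey_cohort.true_depressed.mean() - p) < 3 * se

    def test_invalid_config_rejected(self):
        cfg = perfect_config()
        cfg.prevalence = 1.5
        with pytest.raises(ValueError):
            simulate_cohort(cfg)


class TestEstimation:
    def test_counts_partition_cohort(self, survey_cohort):
        acc = estimate_strategy_params(survey_cohort, "whooley")
        n = len(survey_cohort)
        n_pos = acc.p_positive.effective_events
        n_tp = acc.p_tp_given_positive.effective_events
        n_tn = acc.p_tn_given_negative.effective_events
        fp = n_pos - n_tp
        fn = (n - n_pos) - n_tn
        assert n_tp + fp + n_tn + fn == n

    @pytest.mark.parametrize("strategy", ["whooley", "epds", "whooley_epds"])
    def test_parameter_recovery_within_three_se(self, survey_cfg, survey_cohort, strategy):
        est = estimate_strategy_params(survey_cohort, strategy)
        expected = expected_strategy_accuracy(survey_cfg, strategy)
        for got, want in zip(est.probability_params(), expected.probability_params()):
            n_cell = got.effective_events / got.mean if got.mean > 0 else 1.0
            se = np.sqrt(want.mean * (1 - want.mean) / n_cell)
            assert abs(got.mean - want.mean) < 3 * se, got.label

    def test_perfect_cohort_estimates_perfect_accuracy(self):
        cohort = simulate_cohort(perfect_config())
        acc = estimate_strategy_params(cohort, "whooley")
        assert acc.p_tp_given_positive.mean == 1.0
        assert acc.p_tn_given_negative.mean == 1.0

    def test_empty_conditioning_cell_raises(self):
        cfg = perfect_config(n=50)
        cfg.prevalence = 0.0  # nobody depressed, nobody screens positive
        cohort = simulate_cohort(cfg)
        with pytest.raises(EstimationError, match="positives"):
            estimate_strategy_params(cohort, "whooley")


class TestMicrosimOracle:
    @pytest.mark.parametrize("strategy", STRATEGIES)
    def test_microsim_converges_to_analytic_tree(self, params, strategy):
        """Cohort-mean QALYs and costs match the tree expectations (3 MC SEs)."""
        cfg = strategy_cohort_config(params, strategy, n_women=200_000, seed=11)
        cohort = simulate_cohort(cfg)
        ms = microsimulate_arm(cohort, strategy, params, np.random.default_rng(42))
        analytic = evaluate_arm(strategy, params)
        # Sampling noise in the cohort's outcome-class frequencies adds to
        # the pathway noise; both scale as 1/sqrt(n) and the per-woman SEs
        # computed from the realised draws capture their sum.
        assert abs(ms.mean_qaly - analytic.mean_qaly) < 3 * ms.se_qaly
        assert abs(ms.mean_cost - analytic.mean_cost) < 3 * ms.se_cost

    def test_degenerate_tree_is_exact(self):
        from antescreen.parameters import apply_overrides

        p = apply_overrides(
            default_parameters(),
            {
                "treatment": {
                    "p_fsh": 1.0,
                    "p_respond_fsh": 1.0,
                    "p_spontaneous": 0.0,
                    "p_later_id": 0.0,
                }
            },
        )
        cohort = simulate_cohort(perfect_config(n=500, seed=1))
        ms = microsimulate_arm(cohort, "whooley", p, np.random.default_rng(0))
        prev = cohort.true_depressed.mean()
        q_rec = p.qalys["depressed_to_nondepressed"].value
        q_well = p.qalys["nondepressed_to_nondepressed"].value
        assert ms.mean_qaly == pytest.approx(prev * q_rec + (1 - prev) * q_well)
        expected_cost = (
            p.costs.screen_cost["whooley"].mean
            + prev * p.costs.c_fsh.mean
            + p.costs.other_care_nondepressed.mean
        )
        assert ms.mean_cost == pytest.approx(expected_cost)

    def test_pathway_flags_are_consistent(self, params, survey_cohort):
        ms = microsimulate_arm(
            survey_cohort.head(20_000), "whooley", params, np.random.default_rng(7)
        )
        r = ms.records
        treated = r.screen_positive | r.later_identified
        assert not (r.responded & ~treated).any()
        assert not (r.spontaneously_recovered & r.screen_positive).any()
        assert not (r.spontaneously_recovered & ~r.true_depressed).any()
        assert not (r.later_identified & r.spontaneously_recovered).any()
        assert (r.loc[treated, "treatment_modality"].isin(["fsh", "hipt"])).all()
        assert (r.loc[~treated, "treatment_modality"] == "").all()

    def test_standard_error_scales_as_inverse_root_n(self, params):
        cfg_small = strategy_cohort_config(params, "whooley", n_women=20_000, seed=5)
        cfg_big = strategy_cohort_config(params, "whooley", n_women=80_000, seed=5)
        rng = np.random.default_rng(5)
        se_small = microsimulate_arm(simulate_cohort(cfg_small), "whooley", params, rng).se_qaly
        se_big = microsimulate_arm(simulate_cohort(cfg_big), "whooley", params, rng).se_qaly
        assert se_small / se_big == pytest.approx(2.0, rel=0.2)
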