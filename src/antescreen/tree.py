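"""Decision-tree evaluation: expected QALYs and costs per screening strategy.

The tree has two parts.  The screening stage classifies each woman as a
true positive, false positive, true negative or false negative according
to the strategy's accuracy parameters (with a two-stage variant for
Whooley followed by EPDS).  The treatment stage then attaches an expected
QALY and cost to each class:

* true positives enter treatment (facilitated self-help or high-intensity
  therapy) and respond or not;
* false positives accrue the non-depressed QALY and a fraction of
  treatment resources on top of non-depressed other care;
* true negatives accrue the non-depressed QALY and other care;
* false negatives may recover spontaneously, otherwise a fraction is
  identified later and follows the true-positive pathway, and the rest
  remain depressed and untreated.

All arithmetic is plain algebra on parameter means, so the same functions
evaluate vectorised parameter draws (numpy arrays in place of scalars)
during probabilistic sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import STRATEGIES, ModelParameters, StrategyAccuracy

__all__ = [
    "OutcomeDistribution",
    "PathwayValues",
    "ArmResult",
    "outcome_distribution_single",
    "outcome_distribution_two_stage",
    "strategy_outcome_distribution",
    "pathway_values",
    "evaluate_arm",
    "evaluate_all",
    "arms_to_frame",
]


@dataclass
class OutcomeDistribution:
    """Joint probability of the four screening outcome classes."""

    p_tp: float
    p_fp: float
    p_tn: float
    p_fn: float

    def as_tuple(self):
        return (self.p_tp, self.p_fp, self.p_tn, self.p_fn)

    def validate(self) -> None:
        total = self.p_tp + self.p_fp + self.p_tn + self.p_fn
        if not np.all(np.abs(total - 1.0) < 1e-9):
            raise ValueError(f"outcome probabilities sum to {total}, not 1")
        for name, v in zip(("p_tp", "p_fp", "p_tn", "p_fn"), self.as_tuple()):
            if not np.all((np.asarray(v) >= -1e-12) & (np.asarray(v) <= 1 + 1e-12)):
                raise ValueError(f"{name} outside [0, 1]")


@dataclass
class PathwayValues:
    """Expected QALY and cost conditional on each outcome class.

    Costs cover treatment and other health & social care; the screening
    cost is added at the arm level because every woman in an arm incurs it.
    """

    qaly_tp: float
    qaly_fp: float
    qaly_tn: float
    qaly_fn: float
    cost_tp: float
    cost_fp: float
    cost_tn: float
    cost_fn: float


@dataclass
class ArmResult:
    """Per-strategy expected QALYs and total cost per woman."""

    strategy: str
    mean_qaly: float
    mean_cost: float


def _check_prob(name: str, p) -> None:
    if not np.all((np.asarray(p) >= 0) & (np.asarray(p) <= 1)):
        raise ValueError(f"{name} outside [0, 1]")


def outcome_distribution_single(
    p_positive: float, p_tp_given_positive: float, p_tn_given_negative: float
) -> OutcomeDistribution:
    """Outcome distribution for a single-stage screen.

    Complements (false-positive share of positives, false-negative share
    of negatives) are derived, so the four probabilities always sum to 1.
    """
    for name, p in (
        ("p_positive", p_positive),
        ("p_tp_given_positive", p_tp_given_positive),
        ("p_tn_given_negative", p_tn_given_negative),
    ):
        _check_prob(name, p)
    p_tp = p_positive * p_tp_given_positive
    p_fp = p_positive * (1.0 - p_tp_given_positive)
    p_tn = (1.0 - p_positive) * p_tn_given_negative
    p_fn = (1.0 - p_positive) * (1.0 - p_tn_given_negative)
    return OutcomeDistribution(p_tp, p_fp, p_tn, p_fn)


def outcome_distribution_two_stage(acc: StrategyAccuracy) -> OutcomeDistribution:
    """Outcome distribution for the Whooley-then-EPDS two-stage screen.

    Only women positive on both stages count as screen positive.  Women
    negative at stage one, and stage-one positives who screen negative on
    the EPDS, are screen negative, with true/false-negative splits given
    by their respective conditional probabilities.
    """
    if not acc.is_two_stage:
        raise ValueError(f"{acc.strategy}: two-stage fields not populated")
    s1 = acc.p_stage1_positive.mean
    s2 = acc.p_stage2_positive_given_stage1_positive.mean
    tp_both = acc.p_tp_given_both_positive.mean
    tn_s1p_s2n = acc.p_tn_given_stage1pos_stage2neg.mean
    tn_s1n = acc.p_tn_given_stage1_negative.mean
    for name, p in (
        ("p_stage1_positive", s1),
        ("p_stage2_positive_given_stage1_positive", s2),
        ("p_tp_given_both_positive", tp_both),
        ("p_tn_given_stage1pos_stage2neg", tn_s1p_s2n),
        ("p_tn_given_stage1_negative", tn_s1n),
    ):
        _check_prob(name, p)

    p_both = s1 * s2
    p_s1p_s2n = s1 * (1.0 - s2)
    p_s1n = 1.0 - s1

    p_tp = p_both * tp_both
    p_fp = p_both * (1.0 - tp_both)
    p_tn = p_s1p_s2n * tn_s1p_s2n + p_s1n * tn_s1n
    p_fn = p_s1p_s2n * (1.0 - tn_s1p_s2n) + p_s1n * (1.0 - tn_s1n)
    return OutcomeDistribution(p_tp, p_fp, p_tn, p_fn)


def strategy_outcome_distribution(strategy: str, params: ModelParameters) -> OutcomeDistribution:
    """Outcome distribution of a named strategy under ``params``."""
    if strategy not in params.accuracy:
        raise KeyError(f"unknown strategy: {strategy!r}")
    acc = params.accuracy[strategy]
    if acc.is_two_stage:
        return outcome_distribution_two_stage(acc)
    return outcome_distribution_single(
        acc.p_positive.mean, acc.p_tp_given_positive.mean, acc.p_tn_given_negative.mean
    )


def pathway_values(params: ModelParameters) -> PathwayValues:
    """Expected QALY and cost for each outcome class from the treatment pathway."""
    t = params.treatment
    c = params.costs
    q_rec = params.qalys["depressed_to_nondepressed"].value
    q_dep = params.qalys["depressed_to_depressed"].value
    q_well = params.qalys["nondepressed_to_nondepressed"].value

    p_fsh = t.p_fsh.mean
    p_respond = p_fsh * t.p_respond_fsh.mean + (1.0 - p_fsh) * t.p_respond_hipt.mean
    treat_cost = p_fsh * c.c_fsh.mean + (1.0 - p_fsh) * c.c_hipt.mean
    other_dep = c.other_care_depressed.mean
    other_nondep = c.other_care_nondepressed.mean
    p_spont = t.p_spontaneous.mean
    p_later = t.p_later_id.mean

    qaly_tp = p_respond * q_rec + (1.0 - p_respond) * q_dep
    qaly_fp = t.fp_qaly_multiplier * q_well
    qaly_tn = q_well
    qaly_fn = p_spont * q_rec + (1.0 - p_spont) * (
        p_later * qaly_tp + (1.0 - p_later) * q_dep
    )

    cost_tp = treat_cost + p_respond * other_nondep + (1.0 - p_respond) * other_dep
    cost_fp = t.fp_resource_fraction * treat_cost + other_nondep
    cost_tn = other_nondep
    cost_fn = p_spont * other_nondep + (1.0 - p_spont) * (
        p_later * cost_tp + (1.0 - p_later) * other_dep
    )
    return PathwayValues(qaly_tp, qaly_fp, qaly_tn, qaly_fn, cost_tp, cost_fp, cost_tn, cost_fn)


def _arm_qaly_cost(strategy: str, params: ModelParameters):
    """Expected (QALY, cost) for one arm; works elementwise on array draws."""
    dist = strategy_outcome_distribution(strategy, params)
    pv = pathway_values(params)
    mean_qaly = (
        dist.p_tp * pv.qaly_tp
        + dist.p_fp * pv.qaly_fp
        + dist.p_tn * pv.qaly_tn
        + dist.p_fn * pv.qaly_fn
    )
    mean_cost = params.costs.screen_cost[strategy].mean + (
        dist.p_tp * pv.cost_tp
        + dist.p_fp * pv.cost_fp
        + dist.p_tn * pv.cost_tn
        + dist.p_fn * pv.cost_fn
    )
    return mean_qaly, mean_cost


def evaluate_arm(strategy: str, params: ModelParameters) -> ArmResult:
    """Expected QALYs and total cost per woman for one strategy."""
    if strategy not in STRATEGIES:
        raise KeyError(f"unknown strategy: {strategy!r}")
    q, c = _arm_qaly_cost(strategy, params)
    return ArmResult(strategy, float(q), float(c))


def evaluate_all(params: ModelParameters) -> list[ArmResult]:
    """Evaluate all four arms, in the canonical strategy order."""
    return [evaluate_arm(s, params) for s in STRATEGIES]


def arms_to_frame(arms: list[ArmResult]) -> pd.DataFrame:
    """Arm results as a DataFrame (strategy, mean_qaly, mean_cost)."""
    return pd.DataFrame(
        {
            "strategy": [a.strategy for a in arms],
            "mean_qaly": [a.mean_qaly for a in arms],
            "mean_cost": [a.mean_cost for a in arms],
        }
    )
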