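"""Synthetic individual-level cohorts and a microsimulation oracle.

The screening-accuracy parameters of the analytic model summarise a
cross-sectional accuracy survey: women with a gold-standard diagnosis of
major depressive disorder who received both the Whooley questions and the
EPDS.  This module simulates such a cohort woman by woman — true
depression status at a given prevalence, a Whooley result by
sensitivity/specificity, and an EPDS result whose accuracy is conditional
on the Whooley result (the dependence needed to reproduce the two-stage
screening probabilities).  Simple random sampling is used; the survey's
stratified design is summarised only through the target probabilities.

Two purposes:

* **parameter recovery** — re-estimate the strategy-level screening
  probabilities (with raw counts for beta construction) from a cohort and
  check them against the generating values;
* **brute-force oracle** — walk every woman through the full decision
  tree with Bernoulli draws at each chance node and check that cohort
  mean QALYs and costs converge to the analytic tree expectations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import ModelParameters, ProbabilityParam, StrategyAccuracy

__all__ = [
    "CohortConfig",
    "MicrosimResult",
    "implied_screen_characteristics",
    "implied_two_stage_characteristics",
    "survey_cohort_config",
    "strategy_cohort_config",
    "expected_strategy_accuracy",
    "simulate_cohort",
    "estimate_strategy_params",
    "microsimulate_arm",
]


@dataclass
class CohortConfig:
    """Generating parameters for a synthetic accuracy-survey cohort.

    EPDS accuracy is specified conditional on the Whooley result so that
    the within-woman dependence of the two instruments' errors matches the
    two-stage screening probabilities.  The unaided (no-screen) detection
    indicator is simulated from its own sensitivity/specificity.
    """

    n_women: int
    prevalence: float
    whooley_sensitivity: float
    whooley_specificity: float
    epds_sensitivity_given_whooley_pos: float
    epds_specificity_given_whooley_pos: float
    epds_sensitivity_given_whooley_neg: float
    epds_specificity_given_whooley_neg: float
    no_screen_sensitivity: float = 0.0
    no_screen_specificity: float = 1.0
    seed: int | None = None

    def validate(self) -> None:
        if self.n_women < 1:
            raise ValueError("n_women must be >= 1")
        for name in (
            "prevalence",
            "whooley_sensitivity",
            "whooley_specificity",
            "epds_sensitivity_given_whooley_pos",
            "epds_specificity_given_whooley_pos",
            "epds_sensitivity_given_whooley_neg",
            "epds_specificity_given_whooley_neg",
            "no_screen_sensitivity",
            "no_screen_specificity",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")


# ---------------------------------------------------------------------------
# Translating the model's marginal/conditional accuracy blocks into
# (prevalence, sensitivity, specificity) generating parameters
# ---------------------------------------------------------------------------


def implied_screen_characteristics(acc: StrategyAccuracy) -> tuple[float, float, float]:
    """(prevalence, sensitivity, specificity) implied by a single-stage block.

    The block stores P(screen+), P(depressed | +) and P(not depressed | −);
    Bayes' rule recovers the underlying population quantities.
    """
    if acc.is_two_stage:
        raise ValueError("use implied_two_stage_characteristics for the two-stage block")
    p_pos = acc.p_positive.mean
    tp = p_pos * acc.p_tp_given_positive.mean
    fn = (1.0 - p_pos) * (1.0 - acc.p_tn_given_negative.mean)
    prevalence = tp + fn
    sensitivity = tp / prevalence
    specificity = (1.0 - p_pos) * acc.p_tn_given_negative.mean / (1.0 - prevalence)
    return prevalence, sensitivity, specificity


def implied_two_stage_characteristics(acc: StrategyAccuracy) -> dict[str, float]:
    """Generating parameters implied by the two-stage (Whooley→EPDS) block.

    Returns prevalence, Whooley sensitivity/specificity and EPDS
    sensitivity/specificity conditional on a positive Whooley.
    """
    if not acc.is_two_stage:
        raise ValueError("two-stage fields not populated")
    s1 = acc.p_stage1_positive.mean
    s2 = acc.p_stage2_positive_given_stage1_positive.mean
    # Joint cells within the stage1-positive stratum
    p_d_given_s1pos = s2 * acc.p_tp_given_both_positive.mean + (1.0 - s2) * (
        1.0 - acc.p_tn_given_stage1pos_stage2neg.mean
    )
    p_d_given_s1neg = 1.0 - acc.p_tn_given_stage1_negative.mean
    prevalence = s1 * p_d_given_s1pos + (1.0 - s1) * p_d_given_s1neg
    w_sens = s1 * p_d_given_s1pos / prevalence
    w_spec = (1.0 - s1) * acc.p_tn_given_stage1_negative.mean / (1.0 - prevalence)
    e_sens_wpos = s2 * acc.p_tp_given_both_positive.mean / p_d_given_s1pos
    e_spec_wpos = (
        (1.0 - s2) * acc.p_tn_given_stage1pos_stage2neg.mean / (1.0 - p_d_given_s1pos)
    )
    return {
        "prevalence": prevalence,
        "whooley_sensitivity": w_sens,
        "whooley_specificity": w_spec,
        "epds_sensitivity_given_whooley_pos": e_sens_wpos,
        "epds_specificity_given_whooley_pos": e_spec_wpos,
    }


def survey_cohort_config(
    params: ModelParameters, n_women: int, seed: int | None = None
) -> CohortConfig:
    """Joint Whooley/EPDS cohort configuration reproducing the survey blocks.

    Prevalence, Whooley accuracy and EPDS accuracy among Whooley positives
    come from the two-stage block; EPDS accuracy among Whooley negatives is
    solved so the overall EPDS marginal accuracy matches the EPDS-alone
    block.  Unaided detection comes from the no-screen block (applied at
    the cohort prevalence).
    """
    two = implied_two_stage_characteristics(params.accuracy["whooley_epds"])
    prev = two["prevalence"]
    w_sens = two["whooley_sensitivity"]
    w_spec = two["whooley_specificity"]

    _, e_sens, e_spec = implied_screen_characteristics(params.accuracy["epds"])
    p_wpos_d = prev * w_sens
    p_wneg_d = prev * (1.0 - w_sens)
    p_wpos_nd = (1.0 - prev) * (1.0 - w_spec)
    p_wneg_nd = (1.0 - prev) * w_spec
    e_sens_wneg = (e_sens * prev - two["epds_sensitivity_given_whooley_pos"] * p_wpos_d) / p_wneg_d
    e_spec_wneg = (
        e_spec * (1.0 - prev) - two["epds_specificity_given_whooley_pos"] * p_wpos_nd
    ) / p_wneg_nd
    for name, v in (("epds sensitivity | Whooley-", e_sens_wneg), ("epds specificity | Whooley-", e_spec_wneg)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"no admissible joint distribution: {name} = {v}")

    _, ns_sens, ns_spec = implied_screen_characteristics(params.accuracy["no_screen"])
    config = CohortConfig(
        n_women=n_women,
        prevalence=prev,
        whooley_sensitivity=w_sens,
        whooley_specificity=w_spec,
        epds_sensitivity_given_whooley_pos=two["epds_sensitivity_given_whooley_pos"],
        epds_specificity_given_whooley_pos=two["epds_specificity_given_whooley_pos"],
        epds_sensitivity_given_whooley_neg=e_sens_wneg,
        epds_specificity_given_whooley_neg=e_spec_wneg,
        no_screen_sensitivity=ns_sens,
        no_screen_specificity=ns_spec,
        seed=seed,
    )
    config.validate()
    return config


def strategy_cohort_config(
    params: ModelParameters, strategy: str, n_women: int, seed: int | None = None
) -> CohortConfig:
    """Cohort configuration matched to one strategy's accuracy block.

    The source blocks imply slightly different prevalences (they come from
    different studies), so oracle comparisons of a single arm use a cohort
    generated from that arm's own block.  For single-stage strategies the
    test's accuracy is made independent of the Whooley result, which
    leaves its marginal accuracy exactly the block's.
    """
    if strategy == "whooley_epds":
        two = implied_two_stage_characteristics(params.accuracy["whooley_epds"])
        config = CohortConfig(
            n_women=n_women,
            prevalence=two["prevalence"],
            whooley_sensitivity=two["whooley_sensitivity"],
            whooley_specificity=two["whooley_specificity"],
            epds_sensitivity_given_whooley_pos=two["epds_sensitivity_given_whooley_pos"],
            epds_specificity_given_whooley_pos=two["epds_specificity_given_whooley_pos"],
            epds_sensitivity_given_whooley_neg=two["epds_sensitivity_given_whooley_pos"],
            epds_specificity_given_whooley_neg=two["epds_specificity_given_whooley_pos"],
            seed=seed,
        )
    elif strategy in ("whooley", "epds", "no_screen"):
        prev, sens, spec = implied_screen_characteristics(params.accuracy[strategy])
        kwargs = dict(
            n_women=n_women,
            prevalence=prev,
            whooley_sensitivity=0.5,
            whooley_specificity=0.5,
            epds_sensitivity_given_whooley_pos=0.5,
            epds_specificity_given_whooley_pos=0.5,
            epds_sensitivity_given_whooley_neg=0.5,
            epds_specificity_given_whooley_neg=0.5,
            seed=seed,
        )
        if strategy == "whooley":
            kwargs.update(whooley_sensitivity=sens, whooley_specificity=spec)
        elif strategy == "epds":
            kwargs.update(
                epds_sensitivity_given_whooley_pos=sens,
                epds_specificity_given_whooley_pos=spec,
                epds_sensitivity_given_whooley_neg=sens,
                epds_specificity_given_whooley_neg=spec,
            )
        else:
            kwargs.update(no_screen_sensitivity=sens, no_screen_specificity=spec)
        config = CohortConfig(**kwargs)
    else:
        raise KeyError(f"unknown strategy: {strategy!r}")
    config.validate()
    return config


def expected_strategy_accuracy(config: CohortConfig, strategy: str) -> StrategyAccuracy:
    """Analytic strategy accuracy implied by a cohort configuration.

    This is the ground truth that :func:`estimate_strategy_params` should
    recover, and the accuracy block under which the analytic tree matches
    the microsimulation of a cohort generated from ``config``.
    """
    p = config.prevalence

    def single(sens, spec, name):
        p_pos = p * sens + (1.0 - p) * (1.0 - spec)
        p_neg = 1.0 - p_pos
        tp_given_pos = p * sens / p_pos if p_pos > 0 else 0.0
        tn_given_neg = (1.0 - p) * spec / p_neg if p_neg > 0 else 1.0
        return StrategyAccuracy(
            strategy=name,
            p_positive=ProbabilityParam(f"{name} positive", p_pos),
            p_tp_given_positive=ProbabilityParam(f"{name} +|true+", tp_given_pos),
            p_tn_given_negative=ProbabilityParam(f"{name} -|true-", tn_given_neg),
        )

    if strategy == "whooley":
        return single(config.whooley_sensitivity, config.whooley_specificity, "whooley")
    if strategy == "no_screen":
        return single(config.no_screen_sensitivity, config.no_screen_specificity, "no_screen")
    if strategy == "epds":
        w_pos_d = config.whooley_sensitivity
        e_sens = w_pos_d * config.epds_sensitivity_given_whooley_pos + (
            1.0 - w_pos_d
        ) * config.epds_sensitivity_given_whooley_neg
        w_neg_nd = config.whooley_specificity
        e_spec = (1.0 - w_neg_nd) * config.epds_specificity_given_whooley_pos + (
            w_neg_nd
        ) * config.epds_specificity_given_whooley_neg
        return single(e_sens, e_spec, "epds")
    if strategy == "whooley_epds":
        s1 = p * config.whooley_sensitivity + (1.0 - p) * (1.0 - config.whooley_specificity)
        p_d_s1pos = p * config.whooley_sensitivity / s1
        s2 = (
            p_d_s1pos * config.epds_sensitivity_given_whooley_pos
            + (1.0 - p_d_s1pos) * (1.0 - config.epds_specificity_given_whooley_pos)
        )
        tp_both = p_d_s1pos * config.epds_sensitivity_given_whooley_pos / s2
        tn_s1p_s2n = (
            (1.0 - p_d_s1pos) * config.epds_specificity_given_whooley_pos / (1.0 - s2)
        )
        p_d_s1neg = p * (1.0 - config.whooley_sensitivity) / (1.0 - s1)
        return StrategyAccuracy(
            strategy="whooley_epds",
            p_stage1_positive=ProbabilityParam("stage1 positive", s1),
            p_stage2_positive_given_stage1_positive=ProbabilityParam("stage2+|stage1+", s2),
            p_tp_given_both_positive=ProbabilityParam("true+|both+", tp_both),
            p_tn_given_stage1pos_stage2neg=ProbabilityParam("true-|s1+s2-", tn_s1p_s2n),
            p_tn_given_stage1_negative=ProbabilityParam("true-|s1-", 1.0 - p_d_s1neg),
        )
    raise KeyError(f"unknown strategy: {strategy!r}")


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def simulate_cohort(config: CohortConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate one woman per row: truth, Whooley, EPDS and unaided detection."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_women
    depressed = rng.random(n) < config.prevalence

    p_wpos = np.where(depressed, config.whooley_sensitivity, 1.0 - config.whooley_specificity)
    whooley_pos = rng.random(n) < p_wpos

    e_sens = np.where(
        whooley_pos,
        config.epds_sensitivity_given_whooley_pos,
        config.epds_sensitivity_given_whooley_neg,
    )
    e_spec = np.where(
        whooley_pos,
        config.epds_specificity_given_whooley_pos,
        config.epds_specificity_given_whooley_neg,
    )
    p_epos = np.where(depressed, e_sens, 1.0 - e_spec)
    epds_pos = rng.random(n) < p_epos

    p_nspos = np.where(depressed, config.no_screen_sensitivity, 1.0 - config.no_screen_specificity)
    no_screen_pos = rng.random(n) < p_nspos

    return pd.DataFrame(
        {
            "id": np.arange(n),
            "true_depressed": depressed,
            "whooley_positive": whooley_pos,
            "epds_positive": epds_pos,
            "no_screen_positive": no_screen_pos,
        }
    )


class EstimationError(ValueError):
    """Raised when a conditioning cell of the cohort is empty."""


def _proportion(numer: int, denom: int, cell: str) -> tuple[float, float]:
    if denom == 0:
        raise EstimationError(f"conditioning cell empty: {cell}")
    return numer / denom, float(numer)


def estimate_strategy_params(cohort: pd.DataFrame, strategy: str) -> StrategyAccuracy:
    """Observed screening probabilities (with raw counts) for one strategy."""
    if len(cohort) == 0:
        raise EstimationError("cohort is empty")
    d = cohort["true_depressed"].to_numpy()
    if strategy in ("whooley", "epds", "no_screen"):
        col = {"whooley": "whooley_positive", "epds": "epds_positive", "no_screen": "no_screen_positive"}
        pos = cohort[col[strategy]].to_numpy()
        n = len(cohort)
        p_pos, ev_pos = _proportion(int(pos.sum()), n, "all women")
        p_tp, ev_tp = _proportion(int((pos & d).sum()), int(pos.sum()), f"{strategy} positives")
        p_tn, ev_tn = _proportion(int((~pos & ~d).sum()), int((~pos).sum()), f"{strategy} negatives")
        return StrategyAccuracy(
            strategy=strategy,
            p_positive=ProbabilityParam(f"{strategy} positive", p_pos, ev_pos),
            p_tp_given_positive=ProbabilityParam(f"{strategy} true+|+", p_tp, ev_tp),
            p_tn_given_negative=ProbabilityParam(f"{strategy} true-|-", p_tn, ev_tn),
        )
    if strategy == "whooley_epds":
        w = cohort["whooley_positive"].to_numpy()
        e = cohort["epds_positive"].to_numpy()
        n = len(cohort)
        s1, ev_s1 = _proportion(int(w.sum()), n, "all women")
        s2, ev_s2 = _proportion(int((w & e).sum()), int(w.sum()), "Whooley positives")
        tp_both, ev_tp = _proportion(int((w & e & d).sum()), int((w & e).sum()), "both positive")
        tn_s1p_s2n, ev_a = _proportion(
            int((w & ~e & ~d).sum()), int((w & ~e).sum()), "Whooley+ EPDS-"
        )
        tn_s1n, ev_b = _proportion(int((~w & ~d).sum()), int((~w).sum()), "Whooley negatives")
        return StrategyAccuracy(
            strategy="whooley_epds",
            p_stage1_positive=ProbabilityParam("stage1 positive", s1, ev_s1),
            p_stage2_positive_given_stage1_positive=ProbabilityParam("stage2+|stage1+", s2, ev_s2),
            p_tp_given_both_positive=ProbabilityParam("true+|both+", tp_both, ev_tp),
            p_tn_given_stage1pos_stage2neg=ProbabilityParam("true-|s1+s2-", tn_s1p_s2n, ev_a),
            p_tn_given_stage1_negative=ProbabilityParam("true-|s1-", tn_s1n, ev_b),
        )
    raise KeyError(f"unknown strategy: {strategy!r}")


# ---------------------------------------------------------------------------
# Microsimulation oracle
# ---------------------------------------------------------------------------


@dataclass
class MicrosimResult:
    """Per-woman realised outcomes and cohort means for one arm."""

    strategy: str
    records: pd.DataFrame
    mean_qaly: float
    mean_cost: float
    se_qaly: float
    se_cost: float


def _screen_positive(cohort: pd.DataFrame, strategy: str) -> np.ndarray:
    if strategy == "whooley":
        return cohort["whooley_positive"].to_numpy()
    if strategy == "epds":
        return cohort["epds_positive"].to_numpy()
    if strategy == "whooley_epds":
        return (cohort["whooley_positive"] & cohort["epds_positive"]).to_numpy()
    if strategy == "no_screen":
        return cohort["no_screen_positive"].to_numpy()
    raise KeyError(f"unknown strategy: {strategy!r}")


def microsimulate_arm(
    cohort: pd.DataFrame,
    strategy: str,
    params: ModelParameters,
    rng: np.random.Generator,
) -> MicrosimResult:
    """Walk each woman through the decision tree with Bernoulli chance nodes.

    QALY and cost values at the leaves are the base-case pathway values;
    only chance nodes (treatment modality, response, spontaneous recovery,
    later identification) are random, so cohort means converge to the
    analytic tree expectations for the same accuracy parameters.
    """
    params.validate()
    t = params.treatment
    c = params.costs
    q_rec = params.qalys["depressed_to_nondepressed"].value
    q_dep = params.qalys["depressed_to_depressed"].value
    q_well = params.qalys["nondepressed_to_nondepressed"].value
    other_dep = c.other_care_depressed.mean
    other_nondep = c.other_care_nondepressed.mean

    n = len(cohort)
    depressed = cohort["true_depressed"].to_numpy()
    screen_pos = _screen_positive(cohort, strategy)

    fsh = rng.random(n) < t.p_fsh.mean
    respond = np.where(
        fsh, rng.random(n) < t.p_respond_fsh.mean, rng.random(n) < t.p_respond_hipt.mean
    )
    spont = rng.random(n) < t.p_spontaneous.mean
    later = rng.random(n) < t.p_later_id.mean

    treat_cost = np.where(fsh, c.c_fsh.mean, c.c_hipt.mean)

    tp = screen_pos & depressed
    fp = screen_pos & ~depressed
    tn = ~screen_pos & ~depressed
    fn = ~screen_pos & depressed

    # Pathway flags consistent with the tree: everyone who screens positive
    # starts treatment (false positives stop early), response applies to
    # depressed women in treatment (true positives and later-identified
    # false negatives); spontaneous recovery to untreated false negatives.
    spont_rec = fn & spont
    later_id = fn & ~spont & later
    treated = tp | fp | later_id
    responded = (tp | later_id) & respond

    qaly = np.empty(n)
    cost = np.empty(n)

    qaly[tp] = np.where(respond[tp], q_rec, q_dep)
    cost[tp] = treat_cost[tp] + np.where(respond[tp], other_nondep, other_dep)

    qaly[fp] = t.fp_qaly_multiplier * q_well
    cost[fp] = t.fp_resource_fraction * treat_cost[fp] + other_nondep

    qaly[tn] = q_well
    cost[tn] = other_nondep

    qaly[spont_rec] = q_rec
    cost[spont_rec] = other_nondep
    qaly[later_id] = np.where(respond[later_id], q_rec, q_dep)
    cost[later_id] = treat_cost[later_id] + np.where(respond[later_id], other_nondep, other_dep)
    untreated_fn = fn & ~spont & ~later
    qaly[untreated_fn] = q_dep
    cost[untreated_fn] = other_dep

    cost = cost + c.screen_cost[strategy].mean

    records = cohort.copy()
    records["screen_positive"] = screen_pos
    records["treatment_modality"] = np.where(treated, np.where(fsh, "fsh", "hipt"), "")
    records["responded"] = responded
    records["spontaneously_recovered"] = spont_rec
    records["later_identified"] = later_id
    records["qaly"] = qaly
    records["cost"] = cost

    return MicrosimResult(
        strategy=strategy,
        records=records,
        mean_qaly=float(qaly.mean()),
        mean_cost=float(cost.mean()),
        se_qaly=float(qaly.std(ddof=1) / np.sqrt(n)),
        se_cost=float(cost.std(ddof=1) / np.sqrt(n)),
    )
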