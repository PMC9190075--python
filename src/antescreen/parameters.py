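"""Parameters of the antenatal depression screening cost-effectiveness model.

Every quantity the decision tree consumes lives here: screening-accuracy
probabilities for the four strategies (Whooley questions, EPDS, Whooley
followed by EPDS, and no formal screen), the treatment-pathway
probabilities, nine-month QALY trajectories, and unit costs in 2015/16 GBP.
Each uncertain parameter carries the information needed to build its
sampling distribution for probabilistic sensitivity analysis: probabilities
are beta-distributed with the effective (weighted) event count as the first
shape parameter, costs are gamma-distributed with a standard error of 30%
of the mean, and QALY trajectories are beta-distributed by method of
moments.

Composite parameters that the source model derives from primary inputs
(treatment-response probabilities from relative risks, the later-detection
probability from a three-year rate, the weighted two-stage screening cost)
are computed by the functions in this module rather than stored, so that a
change to a primary input propagates.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, fields

import numpy as np
import yaml

__all__ = [
    "STRATEGIES",
    "QALY_ROLES",
    "ProbabilityParam",
    "CostParam",
    "QalyTrajectory",
    "UtilityParam",
    "UtilitySet",
    "StrategyAccuracy",
    "TreatmentParams",
    "CostSet",
    "ModelParameters",
    "ConfigError",
    "ValidationError",
    "response_probability",
    "later_identification_probability",
    "two_stage_screen_cost",
    "beta_from_probability",
    "gamma_from_mean_se",
    "beta_from_mean_se",
    "effective_events_from_ci",
    "default_parameters",
    "load_parameters",
    "apply_overrides",
    "dump_default_config",
]

#: Strategy identifiers, in reporting order.
STRATEGIES = ("whooley", "epds", "whooley_epds", "no_screen")

#: Nine-month QALY trajectory roles.
QALY_ROLES = (
    "depressed_to_nondepressed",
    "depressed_to_depressed",
    "nondepressed_to_nondepressed",
)


class ConfigError(ValueError):
    """Raised for malformed or unknown configuration keys."""


class ValidationError(ValueError):
    """Raised when a parameter set violates its invariants."""


# ---------------------------------------------------------------------------
# Elementary parameter types
# ---------------------------------------------------------------------------


@dataclass
class ProbabilityParam:
    """A probability with its beta sampling distribution.

    ``effective_events`` is the weighted event count underlying the
    estimate; the beta distribution used in PSA is
    ``Beta(effective_events, effective_events * (1 - mean) / mean)``,
    which has exactly ``mean`` as its mean.
    """

    label: str
    mean: float
    effective_events: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    family: str = "beta"

    def validate(self) -> None:
        if not 0.0 <= self.mean <= 1.0:
            raise ValidationError(f"{self.label}: mean {self.mean} outside [0, 1]")
        if self.ci_low is not None and self.ci_high is not None:
            if not self.ci_low <= self.mean <= self.ci_high:
                raise ValidationError(
                    f"{self.label}: mean {self.mean} outside CI "
                    f"[{self.ci_low}, {self.ci_high}]"
                )
        if self.family == "beta" and self.effective_events is not None:
            if self.effective_events <= 0:
                raise ValidationError(f"{self.label}: effective_events must be > 0")

    def beta_shapes(self) -> tuple[float, float]:
        if self.effective_events is None:
            raise ValidationError(f"{self.label}: no effective event count")
        return beta_from_probability(self.mean, self.effective_events)


@dataclass
class CostParam:
    """A cost (GBP, 2015/16 prices) with a gamma sampling distribution.

    The standard error defaults to 30% of the mean.
    """

    label: str
    mean: float
    se: float | None = None
    family: str = "gamma"

    def __post_init__(self) -> None:
        if self.se is None:
            self.se = 0.30 * self.mean

    def validate(self) -> None:
        if self.mean < 0:
            raise ValidationError(f"{self.label}: negative cost {self.mean}")
        if self.mean > 0 and self.se <= 0:
            raise ValidationError(f"{self.label}: se must be > 0")

    def gamma_shapes(self) -> tuple[float, float]:
        return gamma_from_mean_se(self.mean, self.se)


@dataclass
class QalyTrajectory:
    """QALYs accrued over the 9-month horizon for one health trajectory."""

    role: str
    value: float
    se_fraction: float = 0.30

    def validate(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValidationError(f"QALY trajectory {self.role}: {self.value} outside [0, 1]")

    def beta_shapes(self) -> tuple[float, float]:
        return beta_from_mean_se(self.value, self.se_fraction * self.value)


@dataclass
class UtilityParam:
    label: str
    value: float
    se: float

    def validate(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValidationError(f"{self.label}: utility {self.value} outside [0, 1]")


@dataclass
class UtilitySet:
    """EQ-5D utility weights by period and depression status."""

    ante_depressed: UtilityParam
    ante_nondepressed: UtilityParam
    post_depressed: UtilityParam
    post_nondepressed: UtilityParam

    def validate(self) -> None:
        for f in fields(self):
            getattr(self, f.name).validate()


# ---------------------------------------------------------------------------
# Strategy accuracy
# ---------------------------------------------------------------------------


@dataclass
class StrategyAccuracy:
    """Screening accuracy of one strategy, as marginal/conditional probabilities.

    Single-stage strategies use ``p_positive``, ``p_tp_given_positive`` and
    ``p_tn_given_negative``.  The two-stage Whooley-then-EPDS strategy uses
    the ``p_stage*`` fields instead.  Complementary probabilities (e.g. the
    false-positive share of positives) are never stored: they are always
    computed as one minus the stored probability, which keeps every branch
    pair normalised.
    """

    strategy: str
    p_positive: ProbabilityParam | None = None
    p_tp_given_positive: ProbabilityParam | None = None
    p_tn_given_negative: ProbabilityParam | None = None
    # Two-stage extras (whooley_epds only)
    p_stage1_positive: ProbabilityParam | None = None
    p_stage2_positive_given_stage1_positive: ProbabilityParam | None = None
    p_tp_given_both_positive: ProbabilityParam | None = None
    p_tn_given_stage1pos_stage2neg: ProbabilityParam | None = None
    p_tn_given_stage1_negative: ProbabilityParam | None = None

    @property
    def is_two_stage(self) -> bool:
        return self.p_stage1_positive is not None

    def probability_params(self) -> list[ProbabilityParam]:
        return [
            getattr(self, f.name)
            for f in fields(self)
            if f.name != "strategy" and getattr(self, f.name) is not None
        ]

    def validate(self) -> None:
        for p in self.probability_params():
            p.validate()
        if self.strategy == "whooley_epds":
            needed = (
                self.p_stage1_positive,
                self.p_stage2_positive_given_stage1_positive,
                self.p_tp_given_both_positive,
                self.p_tn_given_stage1pos_stage2neg,
                self.p_tn_given_stage1_negative,
            )
            if any(p is None for p in needed):
                raise ConfigError("whooley_epds accuracy is missing two-stage fields")
        else:
            needed = (self.p_positive, self.p_tp_given_positive, self.p_tn_given_negative)
            if any(p is None for p in needed):
                raise ConfigError(f"{self.strategy} accuracy is missing single-stage fields")


# ---------------------------------------------------------------------------
# Treatment pathway
# ---------------------------------------------------------------------------


@dataclass
class TreatmentParams:
    """Treatment-pathway parameters shared by all four strategies.

    Women who screen positive enter IAPT treatment: a proportion ``p_fsh``
    receive facilitated self-help, the remainder a high-intensity
    psychological intervention.  Response probabilities derive from the
    relative risk of no improvement under each modality times the absolute
    risk of no improvement without treatment.  Depressed women who screen
    negative may recover spontaneously; of those who do not, a proportion
    is identified later within the 9-month horizon (scaled linearly from a
    41%-over-36-months detection rate) and then follows the same treatment
    pathway as a true positive.  False positives consume
    ``fp_resource_fraction`` of treatment resources and, in the base case,
    suffer no quality-of-life decrement (``fp_qaly_multiplier`` = 1).
    """

    p_fsh: ProbabilityParam
    rr_fsh: float = 0.73
    rr_hipt: float = 0.48
    ar_no_improvement: float = 0.67
    p_respond_fsh: ProbabilityParam | None = None
    p_respond_hipt: ProbabilityParam | None = None
    p_spontaneous: ProbabilityParam | None = None
    detection_rate_source: float = 0.41
    detection_source_months: float = 36.0
    p_later_id: ProbabilityParam | None = None
    fp_resource_fraction: float = 0.20
    fp_qaly_multiplier: float = 1.0

    @property
    def p_hipt(self) -> float:
        return 1.0 - self.p_fsh.mean

    def validate(self) -> None:
        for name in ("p_fsh", "p_respond_fsh", "p_respond_hipt", "p_spontaneous", "p_later_id"):
            p = getattr(self, name)
            if p is None:
                raise ConfigError(f"treatment parameter {name} missing")
            p.validate()
        if not 0.0 <= self.fp_resource_fraction <= 1.0:
            raise ValidationError("fp_resource_fraction outside [0, 1]")
        if not 0.0 <= self.fp_qaly_multiplier <= 1.0:
            raise ValidationError("fp_qaly_multiplier outside [0, 1]")
        for name in ("rr_fsh", "rr_hipt"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0.0 <= self.ar_no_improvement <= 1.0:
            raise ValidationError("ar_no_improvement outside [0, 1]")


# ---------------------------------------------------------------------------
# Costs
# ---------------------------------------------------------------------------


@dataclass
class CostSet:
    """Unit costs: screening, treatment and other health & social care."""

    midwife_rate_per_min: float
    screen_minutes: dict[str, float]
    screen_cost: dict[str, CostParam]
    c_fsh: CostParam = None
    c_hipt: CostParam = None
    other_care_depressed: CostParam = None
    other_care_nondepressed: CostParam = None

    def validate(self) -> None:
        for s in STRATEGIES:
            if s not in self.screen_cost:
                raise ConfigError(f"screening cost for {s} missing")
            self.screen_cost[s].validate()
        for name in ("c_fsh", "c_hipt", "other_care_depressed", "other_care_nondepressed"):
            getattr(self, name).validate()


# ---------------------------------------------------------------------------
# The aggregate
# ---------------------------------------------------------------------------


@dataclass
class ModelParameters:
    """Complete parameter set for the decision tree."""

    accuracy: dict[str, StrategyAccuracy]
    treatment: TreatmentParams
    costs: CostSet
    utilities: UtilitySet
    qalys: dict[str, QalyTrajectory]
    horizon_months: float = 9.0

    def validate(self) -> "ModelParameters":
        for s in STRATEGIES:
            if s not in self.accuracy:
                raise ConfigError(f"accuracy block for {s} missing")
            self.accuracy[s].validate()
        self.treatment.validate()
        self.costs.validate()
        self.utilities.validate()
        for role in QALY_ROLES:
            if role not in self.qalys:
                raise ConfigError(f"QALY trajectory {role} missing")
            self.qalys[role].validate()
        if self.horizon_months <= 0:
            raise ValidationError("horizon_months must be > 0")
        return self

    def copy(self) -> "ModelParameters":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# Derivation operations
# ---------------------------------------------------------------------------


def response_probability(rr: float, ar: float) -> float:
    """Probability of responding to treatment.

    ``rr`` is the relative risk of no improvement under treatment and
    ``ar`` the absolute risk of no improvement without treatment; the
    response probability is ``1 - rr * ar``.
    """
    if rr < 0:
        raise ValueError("relative risk must be >= 0")
    if not 0.0 <= ar <= 1.0:
        raise ValueError("absolute risk must be in [0, 1]")
    if rr * ar > 1.0:
        raise ValueError(f"rr * ar = {rr * ar} exceeds 1; no valid probability")
    return 1.0 - rr * ar


def later_identification_probability(
    rate: float, source_months: float, horizon_months: float
) -> float:
    """Probability a false negative is identified within the model horizon.

    Scales a detection rate observed over ``source_months`` linearly to
    ``horizon_months``.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if source_months <= 0 or horizon_months <= 0:
        raise ValueError("durations must be > 0")
    p = rate * horizon_months / source_months
    if p > 1.0:
        raise ValueError(f"scaled probability {p} exceeds 1")
    return p


def two_stage_screen_cost(cost_stage1: float, cost_stage2: float, p_stage1_positive: float) -> float:
    """Expected per-woman cost of a two-stage screen.

    Every woman receives stage one; only stage-one positives receive
    stage two.  Accepts scalars or elementwise arrays of draws.
    """
    if np.any(np.asarray(cost_stage1) < 0) or np.any(np.asarray(cost_stage2) < 0):
        raise ValueError("costs must be >= 0")
    p = np.asarray(p_stage1_positive)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p_stage1_positive must be in [0, 1]")
    return cost_stage1 + p_stage1_positive * cost_stage2


def beta_from_probability(mean: float, effective_events: float) -> tuple[float, float]:
    """Beta shapes from a mean and its weighted event count.

    ``alpha`` is the event count itself; ``beta`` is solved so the
    distribution mean equals ``mean``.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"mean {mean} gives a degenerate beta distribution")
    if effective_events <= 0:
        raise ValueError("effective_events must be > 0")
    alpha = effective_events
    beta = effective_events * (1.0 - mean) / mean
    return alpha, beta


def gamma_from_mean_se(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments gamma ``(shape, scale)`` from mean and SE."""
    if mean <= 0 or se <= 0:
        raise ValueError("mean and se must be > 0")
    shape = (mean / se) ** 2
    scale = se * se / mean
    return shape, scale


def beta_from_mean_se(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments beta shapes on [0, 1] from mean and SE.

    Used for QALY trajectories, whose declared distribution is a beta with
    SE equal to 30% of the value.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"mean {mean} gives a degenerate beta distribution")
    var = se * se
    max_var = mean * (1.0 - mean)
    if var >= max_var:
        raise ValueError(f"variance {var} infeasible for a beta with mean {mean}")
    nu = max_var / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def effective_events_from_ci(mean: float, ci_low: float, ci_high: float) -> float:
    """Weighted event count implied by a normal-approximation 95% CI.

    Inverts ``se = sqrt(mean * (1 - mean) / n)`` with ``se`` taken as a
    quarter of... precisely ``(ci_high - ci_low) / (2 * 1.96)``, and
    returns ``mean * n``.  Used where a source prints a CI but no counts.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError("mean must be strictly inside (0, 1)")
    if not ci_low < ci_high:
        raise ValueError("ci_low must be < ci_high")
    se = (ci_high - ci_low) / (2.0 * 1.959963984540054)
    n = mean * (1.0 - mean) / (se * se)
    return mean * n


# ---------------------------------------------------------------------------
# Defaults
# ---------------------------------------------------------------------------


def _p(label, mean, events, lo=None, hi=None):
    return ProbabilityParam(label, mean, events, lo, hi)


def default_parameters() -> ModelParameters:
    """The printed base case.

    Screening accuracies come from the weighted cross-sectional survey
    (Whooley/EPDS blocks) and, for detection without a screening tool,
    from midwives' unaided detection rates.  Treatment, QALY and cost
    inputs are from the published literature as used by the source model.
    """
    accuracy = {
        "whooley": StrategyAccuracy(
            strategy="whooley",
            p_positive=_p("Whooley positive", 0.0909, 906, 0.085, 0.097),
            p_tp_given_positive=_p("Whooley positive - true positive", 0.4530, 410.4, 0.420, 0.485),
            p_tn_given_negative=_p("Whooley negative - true negative", 0.9341, 8460, 0.929, 0.939),
        ),
        "epds": StrategyAccuracy(
            strategy="epds",
            p_positive=_p("EPDS positive", 0.1144, 1138, 0.108, 0.121),
            p_tp_given_positive=_p("EPDS positive - true positive", 0.5188, 590.6, 0.490, 0.548),
            p_tn_given_negative=_p("EPDS negative - true negative", 0.9534, 8398, 0.949, 0.958),
        ),
        "whooley_epds": StrategyAccuracy(
            strategy="whooley_epds",
            p_stage1_positive=_p("Whooley positive (two-stage)", 0.0895, 890.2, 0.084, 0.095),
            p_stage2_positive_given_stage1_positive=_p(
                "Whooley positive, EPDS positive", 0.4114, 366.2, 0.379, 0.444
            ),
            p_tp_given_both_positive=_p(
                "Whooley positive, EPDS positive - true positive", 0.7500, 8460, 0.741, 0.759
            ),
            p_tn_given_stage1pos_stage2neg=_p(
                "Whooley positive, EPDS negative - true negative", 0.7531, 274.6, 0.708, 0.797
            ),
            p_tn_given_stage1_negative=_p(
                "Whooley negative - true negative (two-stage)", 0.9341, 394.6, 0.910, 0.953
            ),
        ),
        "no_screen": StrategyAccuracy(
            strategy="no_screen",
            p_positive=_p("No-screen positive", 0.0438, 6, 0.016, 0.084),
            p_tp_given_positive=_p("No-screen positive - true positive", 0.6667, 4, 0.284, 0.947),
            p_tn_given_negative=_p("No-screen negative - true negative", 0.8855, 116, 0.826, 0.934),
        ),
    }

    treatment = TreatmentParams(
        p_fsh=_p("Facilitated self-help among treated", 0.7921, 79.21, 0.705, 0.864),
        p_respond_fsh=_p(
            "Respond to facilitated self-help",
            response_probability(0.73, 0.67),
            51.09,
            0.413,
            0.607,
        ),
        p_respond_hipt=_p(
            "Respond to high-intensity psychological therapy",
            response_probability(0.48, 0.67),
            67.84,
            0.586,
            0.767,
        ),
        p_spontaneous=_p("Spontaneous recovery", 0.33, 33, 0.242, 0.425),
        p_later_id=_p(
            "Identified as depressed after first antenatal appointment",
            later_identification_probability(0.41, 36.0, 9.0),
            10.25,
            0.050,
            0.166,
        ),
    )

    minutes = {"whooley": 1.71, "epds": 3.54, "no_screen": 3.0}
    costs = CostSet(
        midwife_rate_per_min=2.65,
        screen_minutes=minutes,
        screen_cost={
            "whooley": CostParam("Whooley screen", 4.53),
            "epds": CostParam("EPDS screen", 9.38),
            "whooley_epds": CostParam("Whooley-EPDS screen", 5.37),
            "no_screen": CostParam("No-screen conversation", 7.95),
        },
        c_fsh=CostParam("Facilitated self-help", 759.0),
        c_hipt=CostParam("High-intensity psychological intervention", 3114.0),
        other_care_depressed=CostParam("Other care, depressed", 2005.0),
        other_care_nondepressed=CostParam("Other care, non-depressed", 1680.0),
    )

    utilities = UtilitySet(
        ante_depressed=UtilityParam("Ante-natal depressed", 0.678, 0.04),
        ante_nondepressed=UtilityParam("Ante-natal not depressed", 0.888, 0.01),
        post_depressed=UtilityParam("Post-natal depressed", 0.771, 0.03),
        post_nondepressed=UtilityParam("Post-natal not depressed", 0.907, 0.01),
    )

    qalys = {
        "depressed_to_nondepressed": QalyTrajectory("depressed_to_nondepressed", 0.6553),
        "depressed_to_depressed": QalyTrajectory("depressed_to_depressed", 0.5991),
        "nondepressed_to_nondepressed": QalyTrajectory("nondepressed_to_nondepressed", 0.7422),
    }

    params = ModelParameters(
        accuracy=accuracy,
        treatment=treatment,
        costs=costs,
        utilities=utilities,
        qalys=qalys,
    )
    return params.validate()


# ---------------------------------------------------------------------------
# Configuration overlay
# ---------------------------------------------------------------------------

# Leaves of the config tree map onto attributes of the parameter objects.
# A numeric leaf overrides the mean/value; a mapping leaf may set
# {mean, effective_events, se} explicitly.


def _set_probability(p: ProbabilityParam, value) -> None:
    if isinstance(value, dict):
        unknown = set(value) - {"mean", "effective_events", "ci_low", "ci_high"}
        if unknown:
            raise ConfigError(f"unknown probability fields: {sorted(unknown)}")
        if "mean" in value:
            p.mean = float(value["mean"])
            # A printed CI for the old mean no longer applies.
            p.ci_low = value.get("ci_low")
            p.ci_high = value.get("ci_high")
        if "effective_events" in value:
            p.effective_events = float(value["effective_events"])
    else:
        p.mean = float(value)
        p.ci_low = None
        p.ci_high = None


def _set_cost(c: CostParam, value) -> None:
    if isinstance(value, dict):
        unknown = set(value) - {"mean", "se"}
        if unknown:
            raise ConfigError(f"unknown cost fields: {sorted(unknown)}")
        if "mean" in value:
            c.mean = float(value["mean"])
            c.se = 0.30 * c.mean
        if "se" in value:
            c.se = float(value["se"])
    else:
        c.mean = float(value)
        c.se = 0.30 * c.mean


def apply_overrides(params: ModelParameters, config: dict) -> ModelParameters:
    """Overlay a nested configuration mapping onto a copy of ``params``.

    Unknown keys raise :class:`ConfigError`; the result is revalidated.
    """
    if config is None:
        config = {}
    if not isinstance(config, dict):
        raise ConfigError("configuration root must be a mapping")
    out = params.copy()
    known_top = {"accuracy", "treatment", "costs", "utilities", "qalys", "horizon_months"}
    unknown = set(config) - known_top
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")

    for strat, block in (config.get("accuracy") or {}).items():
        if strat not in out.accuracy:
            raise ConfigError(f"unknown strategy in accuracy block: {strat!r}")
        acc = out.accuracy[strat]
        for key, value in (block or {}).items():
            p = getattr(acc, key, None)
            if not isinstance(p, ProbabilityParam):
                raise ConfigError(f"unknown accuracy parameter: accuracy.{strat}.{key}")
            _set_probability(p, value)

    tp = out.treatment
    prob_fields = {"p_fsh", "p_respond_fsh", "p_respond_hipt", "p_spontaneous", "p_later_id"}
    scalar_fields = {
        "rr_fsh",
        "rr_hipt",
        "ar_no_improvement",
        "detection_rate_source",
        "detection_source_months",
        "fp_resource_fraction",
        "fp_qaly_multiplier",
    }
    for key, value in (config.get("treatment") or {}).items():
        if key in prob_fields:
            _set_probability(getattr(tp, key), value)
        elif key in scalar_fields:
            setattr(tp, key, float(value))
        else:
            raise ConfigError(f"unknown treatment parameter: treatment.{key}")

    cs = out.costs
    for key, value in (config.get("costs") or {}).items():
        if key == "screen_cost":
            for strat, v in (value or {}).items():
                if strat not in cs.screen_cost:
                    raise ConfigError(f"unknown strategy in screen_cost: {strat!r}")
                _set_cost(cs.screen_cost[strat], v)
        elif key in ("c_fsh", "c_hipt", "other_care_depressed", "other_care_nondepressed"):
            _set_cost(getattr(cs, key), value)
        elif key == "midwife_rate_per_min":
            cs.midwife_rate_per_min = float(value)
        elif key == "screen_minutes":
            for strat, v in (value or {}).items():
                if strat not in cs.screen_minutes:
                    raise ConfigError(f"unknown strategy in screen_minutes: {strat!r}")
                cs.screen_minutes[strat] = float(v)
        else:
            raise ConfigError(f"unknown cost parameter: costs.{key}")

    for key, value in (config.get("utilities") or {}).items():
        u = getattr(out.utilities, key, None)
        if not isinstance(u, UtilityParam):
            raise ConfigError(f"unknown utility: utilities.{key}")
        if isinstance(value, dict):
            unknown = set(value) - {"value", "se"}
            if unknown:
                raise ConfigError(f"unknown utility fields: {sorted(unknown)}")
            if "value" in value:
                u.value = float(value["value"])
            if "se" in value:
                u.se = float(value["se"])
        else:
            u.value = float(value)

    for role, value in (config.get("qalys") or {}).items():
        if role not in out.qalys:
            raise ConfigError(f"unknown QALY trajectory: qalys.{role}")
        out.qalys[role].value = float(value)

    if "horizon_months" in config:
        out.horizon_months = float(config["horizon_months"])

    return out.validate()


def load_parameters(config_path) -> ModelParameters:
    """Load defaults overlaid with a YAML configuration file."""
    with open(config_path) as fh:
        config = yaml.safe_load(fh)
    return apply_overrides(default_parameters(), config or {})


def dump_default_config(stream=None) -> str:
    """Write the full default configuration tree as editable YAML."""
    params = default_parameters()
    tree: dict = {"accuracy": {}, "treatment": {}, "costs": {}, "utilities": {}, "qalys": {}}
    for strat in STRATEGIES:
        acc = params.accuracy[strat]
        tree["accuracy"][strat] = {
            f.name: {
                "mean": getattr(acc, f.name).mean,
                "effective_events": getattr(acc, f.name).effective_events,
            }
            for f in fields(acc)
            if f.name != "strategy" and getattr(acc, f.name) is not None
        }
    tp = params.treatment
    for name in ("p_fsh", "p_respond_fsh", "p_respond_hipt", "p_spontaneous", "p_later_id"):
        p = getattr(tp, name)
        tree["treatment"][name] = {"mean": p.mean, "effective_events": p.effective_events}
    for name in (
        "rr_fsh",
        "rr_hipt",
        "ar_no_improvement",
        "detection_rate_source",
        "detection_source_months",
        "fp_resource_fraction",
        "fp_qaly_multiplier",
    ):
        tree["treatment"][name] = getattr(tp, name)
    cs = params.costs
    tree["costs"] = {
        "midwife_rate_per_min": cs.midwife_rate_per_min,
        "screen_minutes": dict(cs.screen_minutes),
        "screen_cost": {s: {"mean": cs.screen_cost[s].mean, "se": cs.screen_cost[s].se} for s in STRATEGIES},
        "c_fsh": {"mean": cs.c_fsh.mean, "se": cs.c_fsh.se},
        "c_hipt": {"mean": cs.c_hipt.mean, "se": cs.c_hipt.se},
        "other_care_depressed": {"mean": cs.other_care_depressed.mean, "se": cs.other_care_depressed.se},
        "other_care_nondepressed": {
            "mean": cs.other_care_nondepressed.mean,
            "se": cs.other_care_nondepressed.se,
        },
    }
    for name in ("ante_depressed", "ante_nondepressed", "post_depressed", "post_nondepressed"):
        u = getattr(params.utilities, name)
        tree["utilities"][name] = {"value": u.value, "se": u.se}
    for role in QALY_ROLES:
        tree["qalys"][role] = params.qalys[role].value
    tree["horizon_months"] = params.horizon_months

    text = yaml.safe_dump(tree, sort_keys=False)
    if stream is not None:
        stream.write(text)
    return text
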