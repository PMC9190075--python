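"""One-way sensitivity analyses.

Thirteen deterministic scenarios (1a–7b) probe the assumptions the base
case rests on: the accuracy and cost of detection without a screening
tool, the treatment-modality mix, the later-identification rate, a
quality-of-life decrement for false positives, the depressed-state
utilities, the resource use of false positives, and the spontaneous
recovery rate.  Each scenario is a declarative set of parameter overrides
applied to a copy of the base case; overridden probabilities keep their
effective-event dispersion (re-centred betas) and overridden costs keep
the 30%-of-mean standard-error rule, so every scenario can be run
probabilistically as well as deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import economics, psa, tree
from .parameters import (
    ModelParameters,
    apply_overrides,
    default_parameters,
    effective_events_from_ci,
)

__all__ = [
    "SCENARIO_IDS",
    "Scenario",
    "ScenarioResult",
    "builtin_scenarios",
    "apply_scenario",
    "run_scenarios",
]

SCENARIO_IDS = ("1a", "1b", "2a", "2b", "3a", "3b", "4", "5a", "5b", "6a", "6b", "7a", "7b")

# Detection of depression by GPs (meta-analytic sensitivity 50.1%,
# specificity 81.3%), expressed in the model's marginal/conditional form,
# with event counts recovered from the printed confidence intervals.
_GP_DETECTION = {
    "p_positive": {"mean": 0.2500, "ci": (0.171, 0.339)},
    "p_tp_given_positive": {"mean": 0.4000, "ci": (0.221, 0.594)},
    "p_tn_given_negative": {"mean": 0.8667, "ci": (0.782, 0.933)},
}
_GP_CONTACT_COST = 31.0  # one GP appointment, 9.22 minutes


@dataclass
class Scenario:
    """A named set of parameter overrides on top of the base case."""

    id: str
    description: str
    overrides: dict = field(default_factory=dict)


def _gp_detection_overrides() -> dict:
    block = {}
    for name, spec in _GP_DETECTION.items():
        lo, hi = spec["ci"]
        block[name] = {
            "mean": spec["mean"],
            "effective_events": effective_events_from_ci(spec["mean"], lo, hi),
        }
    return block


def _utility_scenario(scale: float) -> dict:
    """Scale the depressed-state utilities and rescale QALY trajectories.

    The printed nine-month QALY trajectories cannot be recomputed exactly
    from the utilities (the transition-timing assumption behind them is
    not recoverable), so they are moved multiplicatively by the ratio of
    an area-under-the-curve proxy — six months at the antenatal utility
    plus three months at the postnatal utility, in years — evaluated at
    the adjusted versus base utilities.  The depressed-to-non-depressed
    trajectory rescales its antenatal (depressed) component only.
    """
    base = default_parameters()
    u = base.utilities
    ante_dep = u.ante_depressed.value * scale
    post_dep = u.post_depressed.value * scale

    def proxy(ante, post):
        return (6.0 * ante + 3.0 * post) / 12.0

    dep_dep_ratio = proxy(ante_dep, post_dep) / proxy(u.ante_depressed.value, u.post_depressed.value)
    dep_rec_ratio = proxy(ante_dep, u.post_nondepressed.value) / proxy(
        u.ante_depressed.value, u.post_nondepressed.value
    )
    return {
        "utilities": {"ante_depressed": ante_dep, "post_depressed": post_dep},
        "qalys": {
            "depressed_to_depressed": base.qalys["depressed_to_depressed"].value * dep_dep_ratio,
            "depressed_to_nondepressed": base.qalys["depressed_to_nondepressed"].value
            * dep_rec_ratio,
        },
    }


def builtin_scenarios() -> list[Scenario]:
    """The thirteen one-way sensitivity scenarios."""
    gp = _gp_detection_overrides()
    return [
        Scenario(
            "1a",
            "No-screen detection from GP accuracy data; GP contact cost £31",
            {
                "accuracy": {"no_screen": gp},
                "costs": {"screen_cost": {"no_screen": _GP_CONTACT_COST}},
            },
        ),
        Scenario(
            "1b",
            "As 1a but with the no-screen contact cost set to £0",
            {
                "accuracy": {"no_screen": gp},
                "costs": {"screen_cost": {"no_screen": 0.0}},
            },
        ),
        Scenario(
            "2a",
            "All treated women receive facilitated self-help",
            {"treatment": {"p_fsh": 1.0}},
        ),
        Scenario(
            "2b",
            "All treated women receive high-intensity psychological therapy",
            {"treatment": {"p_fsh": 0.0}},
        ),
        Scenario("3a", "Later identification of false negatives 5%", {"treatment": {"p_later_id": 0.05}}),
        Scenario("3b", "Later identification of false negatives 20%", {"treatment": {"p_later_id": 0.20}}),
        Scenario(
            "4",
            "2% quality-of-life reduction for false positives",
            {"treatment": {"fp_qaly_multiplier": 0.98}},
        ),
        Scenario("5a", "Depressed-state utilities increased by 15%", _utility_scenario(1.15)),
        Scenario("5b", "Depressed-state utilities decreased by 15%", _utility_scenario(0.85)),
        Scenario(
            "6a",
            "False positives use 10% of treatment resources",
            {"treatment": {"fp_resource_fraction": 0.10}},
        ),
        Scenario(
            "6b",
            "False positives use 30% of treatment resources",
            {"treatment": {"fp_resource_fraction": 0.30}},
        ),
        Scenario("7a", "Spontaneous recovery rate 0%", {"treatment": {"p_spontaneous": 0.0}}),
        Scenario("7b", "Spontaneous recovery rate 50%", {"treatment": {"p_spontaneous": 0.50}}),
    ]


def scenario_by_id(scenario_id: str) -> Scenario:
    for s in builtin_scenarios():
        if s.id == scenario_id:
            return s
    raise KeyError(f"unknown scenario id {scenario_id!r}; valid ids: {', '.join(SCENARIO_IDS)}")


def apply_scenario(params: ModelParameters, scenario: Scenario) -> ModelParameters:
    """Return a new parameter set with the scenario's overrides applied.

    The input ``params`` is never mutated; overridden probabilities are
    re-centred on the new means with unchanged effective-event counts
    (unless the scenario supplies its own) and overridden costs fall back
    to the 30%-of-mean standard error.
    """
    return apply_overrides(params, scenario.overrides)


@dataclass
class ScenarioResult:
    """Base-case and probabilistic results for one scenario."""

    scenario_id: str
    description: str
    arms: list[tree.ArmResult]
    incremental: list[economics.IncrementalRow]
    frontier: economics.Frontier
    ceac: psa.CeacTable | None = None
    draws: psa.PsaDraws | None = None


def run_scenarios(
    params: ModelParameters,
    scenarios: list[Scenario] | None = None,
    n_iterations: int = 5000,
    seed: int | None = None,
    lambda_grid=psa.DEFAULT_LAMBDA_GRID,
    include_base: bool = True,
    keep_draws: bool = False,
) -> dict[str, ScenarioResult]:
    """Deterministic and probabilistic results for each scenario.

    Each scenario gets an independent random stream spawned from ``seed``,
    so results are reproducible and insensitive to the subset of scenarios
    run.  The unmodified base case is included under id ``"base"``.
    """
    if scenarios is None:
        scenarios = builtin_scenarios()
    jobs = []
    if include_base:
        jobs.append(Scenario("base", "Base case", {}))
    jobs.extend(scenarios)

    root = np.random.SeedSequence(seed)
    children = root.spawn(len(jobs))

    results: dict[str, ScenarioResult] = {}
    for scen, child in zip(jobs, children):
        scen_params = apply_scenario(params, scen)
        arms = tree.evaluate_all(scen_params)
        incremental = economics.incremental_vs_reference(arms, "no_screen")
        frontier = economics.dominance_frontier(arms)
        ceac_table = None
        draws = None
        if n_iterations:
            draws = psa.run_psa(scen_params, n_iterations=n_iterations, seed=child)
            ceac_table = psa.ceac(draws, lambda_grid)
        results[scen.id] = ScenarioResult(
            scenario_id=scen.id,
            description=scen.description,
            arms=arms,
            incremental=incremental,
            frontier=frontier,
            ceac=ceac_table,
            draws=draws if keep_draws else None,
        )
    return results
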