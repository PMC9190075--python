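"""High-level modelling interface.

:class:`ScreeningModel` bundles a parameter set with the operations a
user typically chains: deterministic tree evaluation (:meth:`fit`),
probabilistic sensitivity analysis (:meth:`fit_psa`) and the scenario
battery (:meth:`fit_scenarios`).  Results objects carry the estimates and
render compact text summaries; the underlying functional modules
(:mod:`~antescreen.tree`, :mod:`~antescreen.economics`,
:mod:`~antescreen.psa`, :mod:`~antescreen.scenarios`) remain usable on
their own.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import economics, psa, scenarios, tree
from .parameters import ModelParameters, default_parameters, load_parameters

__all__ = ["ScreeningModel", "DecisionTreeResults", "PsaResults"]


@dataclass
class DecisionTreeResults:
    """Deterministic results: arm means, incremental table and frontier."""

    params: ModelParameters
    arms: list[tree.ArmResult]
    incremental: list[economics.IncrementalRow]
    frontier: economics.Frontier
    reference: str

    @property
    def arms_frame(self) -> pd.DataFrame:
        return tree.arms_to_frame(self.arms)

    @property
    def incremental_frame(self) -> pd.DataFrame:
        return economics.incremental_to_frame(self.incremental)

    def summary(self) -> str:
        """Human-readable results table (QALYs to 4 dp, costs in whole pounds)."""
        lines = ["Screening strategy comparison (per woman, 9-month horizon)", ""]
        lines.append(f"{'strategy':<14}{'QALYs':>8}{'cost £':>9}  status")
        for arm in sorted(self.arms, key=lambda a: -a.mean_qaly):
            status = self.frontier.status[arm.strategy]
            lines.append(
                f"{arm.strategy:<14}{arm.mean_qaly:>8.4f}{arm.mean_cost:>9.0f}  {status}"
            )
        lines.append("")
        lines.append(f"Incremental analysis vs {self.reference}:")
        for row in self.incremental:
            icer = "undefined" if row.icer is None else f"£{row.icer:,.0f}/QALY"
            lines.append(
                f"  {row.strategy:<14} ΔQALY {row.delta_qaly:+.4f}  "
                f"Δcost £{row.delta_cost:+,.0f}  ICER {icer}"
            )
        chain = " -> ".join(self.frontier.strategies)
        lines.append(f"Frontier: {chain}")
        if self.frontier.icers:
            icers = ", ".join(f"£{v:,.0f}/QALY" for v in self.frontier.icers)
            lines.append(f"Frontier ICERs: {icers}")
        return "\n".join(lines)


@dataclass
class PsaResults:
    """Probabilistic results: draw table plus CEAC/plane summaries."""

    params: ModelParameters
    draws: psa.PsaDraws

    def ceac(self, lambda_grid=psa.DEFAULT_LAMBDA_GRID) -> psa.CeacTable:
        return psa.ceac(self.draws, lambda_grid)

    def ce_plane(self, reference: str = "no_screen") -> pd.DataFrame:
        return psa.ce_plane(self.draws, reference)

    def convergence(self, wtp: float = 20000.0, block_count: int = 10) -> float:
        return psa.convergence_check(self.draws, wtp, block_count)

    def summary(self, wtp: float = 20000.0) -> str:
        table = psa.ceac(self.draws, [wtp])
        lines = [
            f"PSA with {self.draws.n_iterations} iterations "
            f"(probability cost-effective at £{wtp:,.0f}/QALY):"
        ]
        for s in table.probabilities.columns:
            lines.append(f"  {s:<14}{table.probabilities[s].iloc[0]:.3f}")
        return "\n".join(lines)


class ScreeningModel:
    """Decision-tree cost-effectiveness model of antenatal depression screening.

    Parameters default to the printed base case; pass a custom
    :class:`~antescreen.parameters.ModelParameters` or use
    :meth:`from_config` to overlay a YAML configuration file.
    """

    def __init__(self, params: ModelParameters | None = None):
        self.params = (params or default_parameters()).validate()

    @classmethod
    def from_config(cls, config_path) -> "ScreeningModel":
        return cls(load_parameters(config_path))

    def fit(self, reference: str = "no_screen") -> DecisionTreeResults:
        arms = tree.evaluate_all(self.params)
        return DecisionTreeResults(
            params=self.params,
            arms=arms,
            incremental=economics.incremental_vs_reference(arms, reference),
            frontier=economics.dominance_frontier(arms),
            reference=reference,
        )

    def fit_psa(self, n_iterations: int = 5000, seed: int | None = None) -> PsaResults:
        draws = psa.run_psa(self.params, n_iterations=n_iterations, seed=seed)
        return PsaResults(params=self.params, draws=draws)

    def fit_scenarios(self, ids=None, n_iterations: int = 5000, seed: int | None = None):
        if ids is None:
            scen = scenarios.builtin_scenarios()
        else:
            scen = [scenarios.scenario_by_id(i) for i in ids]
        return scenarios.run_scenarios(
            self.params, scen, n_iterations=n_iterations, seed=seed
        )
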