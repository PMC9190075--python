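"""Incremental cost-effectiveness analysis.

Given per-arm expected QALYs and costs, this module computes incremental
cost-effectiveness ratios (ICERs) against a reference arm, classifies arms
by the rules of dominance and extended dominance to obtain the efficiency
frontier, and evaluates net monetary benefit (NMB).

Two ICER conventions are exposed.  The library default divides
full-precision deltas.  The *rounded-delta* convention first rounds the
incremental cost to whole pounds and the incremental QALYs to four decimal
places and then divides, which is how the headline ratios in published
tables of this kind are typically printed; use ``rounded=True`` for
comparisons against such tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .tree import ArmResult

__all__ = [
    "IncrementalRow",
    "Frontier",
    "icer",
    "incremental_vs_reference",
    "dominance_frontier",
    "net_monetary_benefit",
    "incremental_to_frame",
]

#: Arm classifications used in :class:`IncrementalRow` and :class:`Frontier`.
ON_FRONTIER = "on_frontier"
DOMINATED = "dominated"
EXTENDED_DOMINATED = "extended_dominated"
REFERENCE = "reference"


@dataclass
class IncrementalRow:
    """One pairwise comparison against a reference arm.

    ``icer`` is ``None`` when the incremental QALYs are zero (the ratio is
    undefined); a negative ICER is sign-ambiguous on its own, so consult
    ``delta_qaly``/``delta_cost`` (or the frontier status) to tell dominance
    from being dominated.
    """

    strategy: str
    reference: str
    delta_qaly: float
    delta_cost: float
    icer: float | None
    status: str = ""


@dataclass
class Frontier:
    """Cost-effectiveness frontier: undominated strategies and adjacent ICERs.

    ``strategies`` is ordered by increasing cost (and QALYs); ``icers`` has
    one entry per adjacent pair and is strictly increasing.  ``status``
    maps every input strategy to its classification, and ``ties`` lists
    groups of strategies with identical (cost, QALY).
    """

    strategies: list[str]
    icers: list[float]
    status: dict[str, str]
    ties: list[tuple[str, ...]]


def icer(delta_cost: float, delta_qaly: float, rounded: bool = False) -> float | None:
    """Incremental cost-effectiveness ratio, or ``None`` if ΔQALY is zero.

    With ``rounded=True``, applies the rounded-delta printing convention
    (ΔC to whole pounds, ΔQ to 4 decimal places) before dividing.
    """
    if rounded:
        delta_cost = round(delta_cost)
        delta_qaly = round(delta_qaly, 4)
    if delta_qaly == 0:
        return None
    return delta_cost / delta_qaly


def incremental_vs_reference(
    arms: list[ArmResult], reference: str, rounded: bool = False
) -> list[IncrementalRow]:
    """One incremental row per non-reference arm, versus ``reference``."""
    by_name = {a.strategy: a for a in arms}
    if reference not in by_name:
        raise KeyError(f"reference strategy {reference!r} not among arms")
    ref = by_name[reference]
    frontier = dominance_frontier(arms)
    rows = []
    for arm in arms:
        if arm.strategy == reference:
            continue
        dq = arm.mean_qaly - ref.mean_qaly
        dc = arm.mean_cost - ref.mean_cost
        rows.append(
            IncrementalRow(
                strategy=arm.strategy,
                reference=reference,
                delta_qaly=dq,
                delta_cost=dc,
                icer=icer(dc, dq, rounded=rounded),
                status=frontier.status[arm.strategy],
            )
        )
    return rows


def dominance_frontier(arms: list[ArmResult]) -> Frontier:
    """Classify arms by strict and extended dominance.

    Arms are sorted by ascending cost; an arm is *dominated* when some
    other arm has cost <= and QALYs >= with at least one strict
    inequality.  Among the survivors, arms are removed as *extended
    dominated* while any adjacent pair of incremental ICERs fails to
    increase strictly, i.e. when a mixture of the arm's neighbours would
    deliver more QALYs at lower cost.  Arms with identical (cost, QALY)
    tie: neither dominates the other, both stay on the frontier.
    """
    if len(arms) < 2:
        raise ValueError("need at least two arms")
    status = {a.strategy: ON_FRONTIER for a in arms}

    for a in arms:
        for b in arms:
            if a is b:
                continue
            if (
                b.mean_cost <= a.mean_cost
                and b.mean_qaly >= a.mean_qaly
                and (b.mean_cost < a.mean_cost or b.mean_qaly > a.mean_qaly)
            ):
                status[a.strategy] = DOMINATED
                break

    survivors = [a for a in arms if status[a.strategy] == ON_FRONTIER]
    survivors.sort(key=lambda a: (a.mean_cost, a.mean_qaly))

    # Collapse exact ties to a single representative for the ICER chain.
    ties: list[tuple[str, ...]] = []
    chain: list[ArmResult] = []
    for a in survivors:
        if chain and math.isclose(a.mean_cost, chain[-1].mean_cost, abs_tol=0.0) and math.isclose(
            a.mean_qaly, chain[-1].mean_qaly, abs_tol=0.0
        ):
            if ties and chain[-1].strategy in ties[-1]:
                ties[-1] = ties[-1] + (a.strategy,)
            else:
                ties.append((chain[-1].strategy, a.strategy))
        else:
            chain.append(a)

    # Extended dominance: drop interior arms until adjacent ICERs strictly increase.
    changed = True
    while changed and len(chain) > 2:
        changed = False
        for i in range(1, len(chain) - 1):
            lo, mid, hi = chain[i - 1], chain[i], chain[i + 1]
            icer_in = icer(mid.mean_cost - lo.mean_cost, mid.mean_qaly - lo.mean_qaly)
            icer_out = icer(hi.mean_cost - mid.mean_cost, hi.mean_qaly - mid.mean_qaly)
            if icer_in is None or (icer_out is not None and icer_out <= icer_in):
                status[mid.strategy] = EXTENDED_DOMINATED
                del chain[i]
                changed = True
                break

    icers = [
        icer(b.mean_cost - a.mean_cost, b.mean_qaly - a.mean_qaly)
        for a, b in zip(chain, chain[1:])
    ]
    frontier_names = [a.strategy for a in chain]
    for group in ties:
        for name in group:
            if name not in frontier_names and status[name] == ON_FRONTIER:
                frontier_names.append(name)
    return Frontier(strategies=frontier_names, icers=icers, status=status, ties=ties)


def net_monetary_benefit(qaly: float, cost: float, wtp: float) -> float:
    """Net monetary benefit ``wtp * qaly - cost`` at willingness-to-pay ``wtp``."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * qaly - cost


def incremental_to_frame(rows: list[IncrementalRow]) -> pd.DataFrame:
    """Incremental table as a DataFrame."""
    return pd.DataFrame(
        {
            "strategy": [r.strategy for r in rows],
            "reference": [r.reference for r in rows],
            "delta_qaly": [r.delta_qaly for r in rows],
            "delta_cost": [r.delta_cost for r in rows],
            "icer": [r.icer for r in rows],
            "status": [r.status for r in rows],
        }
    )
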