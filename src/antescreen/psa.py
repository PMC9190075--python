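"""Probabilistic sensitivity analysis.

Each PSA iteration draws every uncertain parameter from its sampling
distribution — betas for probabilities (shape ``(events, events(1-m)/m)``
so the mean is preserved), gammas for costs (method of moments with
SE = 30% of the mean), betas by method of moments for the QALY
trajectories — and re-evaluates the decision tree.  Each arm's
cost-outcome column is sampled independently by default (see
:func:`run_psa` for the alternative of common draws across arms).
Derived quantities (the weighted
two-stage screening cost, all pathway composites) are recomputed from the
draws each iteration; structural constants (the false-positive resource
fraction, the horizon) do not vary.

Results are summarised as cost-effectiveness acceptability curves (CEACs:
the probability each arm attains the maximal net monetary benefit, over a
willingness-to-pay grid) and cost-effectiveness planes (per-iteration
incremental scatter against a reference arm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import (
    QALY_ROLES,
    STRATEGIES,
    ModelParameters,
    ProbabilityParam,
    two_stage_screen_cost,
)
from .tree import _arm_qaly_cost

__all__ = [
    "DEFAULT_LAMBDA_GRID",
    "PsaDraws",
    "CeacTable",
    "sample_parameters",
    "run_psa",
    "ceac",
    "ce_plane",
    "convergence_check",
]

#: Default willingness-to-pay grid: £0–£50,000 per QALY in £1,000 steps,
#: covering the NICE £20,000–£30,000 decision band.
DEFAULT_LAMBDA_GRID = tuple(range(0, 50001, 1000))

# Stable draw order: accuracy fields per strategy, then treatment, QALYs, costs.
_ACCURACY_FIELDS = (
    "p_positive",
    "p_tp_given_positive",
    "p_tn_given_negative",
    "p_stage1_positive",
    "p_stage2_positive_given_stage1_positive",
    "p_tp_given_both_positive",
    "p_tn_given_stage1pos_stage2neg",
    "p_tn_given_stage1_negative",
)
_TREATMENT_PROBS = ("p_fsh", "p_respond_fsh", "p_respond_hipt", "p_spontaneous", "p_later_id")
_COST_FIELDS = ("c_fsh", "c_hipt", "other_care_depressed", "other_care_nondepressed")


@dataclass
class PsaDraws:
    """Per-iteration, per-arm sampled (QALY, cost) table."""

    n_iterations: int
    seed: int | None
    qalys: pd.DataFrame  # n_iterations rows, one column per strategy
    costs: pd.DataFrame

    def validate(self) -> None:
        for df in (self.qalys, self.costs):
            if list(df.columns) != list(STRATEGIES) or len(df) != self.n_iterations:
                raise ValueError("draw table incomplete")
            if df.isna().any().any():
                raise ValueError("draw table has missing cells")
        if ((self.qalys < 0) | (self.qalys > 1)).any().any():
            raise ValueError("QALY draws outside [0, 1]")
        if (self.costs < 0).any().any():
            raise ValueError("negative cost draws")

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: iteration, strategy, qaly, cost."""
        rows = []
        for s in STRATEGIES:
            rows.append(
                pd.DataFrame(
                    {
                        "iteration": np.arange(self.n_iterations),
                        "strategy": s,
                        "qaly": self.qalys[s].to_numpy(),
                        "cost": self.costs[s].to_numpy(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, seed: int | None = None) -> "PsaDraws":
        """Rebuild from a :meth:`to_frame` table (deterministic re-summarisation)."""
        qalys = frame.pivot(index="iteration", columns="strategy", values="qaly")
        costs = frame.pivot(index="iteration", columns="strategy", values="cost")
        qalys = qalys[list(STRATEGIES)].reset_index(drop=True)
        costs = costs[list(STRATEGIES)].reset_index(drop=True)
        qalys.columns.name = costs.columns.name = None
        out = cls(n_iterations=len(qalys), seed=seed, qalys=qalys, costs=costs)
        out.validate()
        return out


@dataclass
class CeacTable:
    """Probability each arm is cost-effective over a willingness-to-pay grid."""

    lambdas: np.ndarray
    probabilities: pd.DataFrame  # one row per lambda, one column per strategy

    def validate(self) -> None:
        sums = self.probabilities.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("CEAC rows do not sum to 1")

    def to_frame(self) -> pd.DataFrame:
        out = self.probabilities.copy()
        out.insert(0, "lambda", self.lambdas)
        return out


def _draw_probability(p: ProbabilityParam, rng: np.random.Generator, size):
    """Beta draw preserving the mean; degenerate means are kept fixed."""
    if p.mean <= 0.0 or p.mean >= 1.0 or p.effective_events is None:
        return p.mean if size is None else np.full(size, p.mean)
    a, b = p.beta_shapes()
    return rng.beta(a, b, size=size)


def _draw_cost(mean: float, se: float, rng: np.random.Generator, size):
    if mean <= 0.0:
        return mean if size is None else np.full(size, mean)
    shape = (mean / se) ** 2
    scale = se * se / mean
    return rng.gamma(shape, scale, size=size)


def _draw_qaly(value: float, se_fraction: float, rng: np.random.Generator, size):
    if value <= 0.0 or value >= 1.0:
        return value if size is None else np.full(size, value)
    se = se_fraction * value
    var = se * se
    nu = value * (1.0 - value) / var - 1.0
    if nu <= 0:
        raise ValueError(f"QALY variance {var} infeasible for a beta with mean {value}")
    return rng.beta(value * nu, (1.0 - value) * nu, size=size)


def sample_parameters(
    params: ModelParameters, rng: np.random.Generator, size: int | None = None
) -> ModelParameters:
    """One parameter draw (or, with ``size``, a vectorised batch of draws).

    Returns a copy of ``params`` whose uncertain means are replaced by
    sampled values; with ``size`` set, each mean becomes an array of
    ``size`` draws and the decision tree evaluates all of them at once.
    """
    out = params.copy()
    for strat in STRATEGIES:
        acc = out.accuracy[strat]
        for name in _ACCURACY_FIELDS:
            p = getattr(acc, name)
            if p is not None:
                p.mean = _draw_probability(p, rng, size)
    t = out.treatment
    for name in _TREATMENT_PROBS:
        p = getattr(t, name)
        p.mean = _draw_probability(p, rng, size)
    for role in QALY_ROLES:
        q = out.qalys[role]
        q.value = _draw_qaly(q.value, q.se_fraction, rng, size)
    c = out.costs
    for strat in ("whooley", "epds", "no_screen"):
        sc = c.screen_cost[strat]
        sc.mean = _draw_cost(sc.mean, sc.se, rng, size)
    for name in _COST_FIELDS:
        cp = getattr(c, name)
        cp.mean = _draw_cost(cp.mean, cp.se, rng, size)
    # Derived: the two-stage screening cost is recomputed from the drawn
    # stage costs and the drawn probability of a positive first stage.
    c.screen_cost["whooley_epds"].mean = two_stage_screen_cost(
        c.screen_cost["whooley"].mean,
        c.screen_cost["epds"].mean,
        out.accuracy["whooley_epds"].p_stage1_positive.mean,
    )
    return out


def run_psa(
    params: ModelParameters,
    n_iterations: int = 5000,
    seed: int | np.random.SeedSequence | None = None,
    common_draws: bool = False,
) -> PsaDraws:
    """Propagate parameter uncertainty through the tree ``n_iterations`` times.

    By default each arm's cost-outcome column is generated from its own
    independent draws of *all* uncertain parameters, which matches
    net-benefit analyses of per-arm Monte Carlo cost-outcome data (and is
    what makes incremental scatters spread over all four quadrants of the
    cost-effectiveness plane).  With ``common_draws=True`` the four arms
    share one parameter draw per iteration instead, isolating the
    between-arm contrast from parameters the arms have in common.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    qalys = {}
    costs = {}
    if common_draws:
        drawn = sample_parameters(params, np.random.default_rng(ss), size=n_iterations)
        for s in STRATEGIES:
            q, c = _arm_qaly_cost(s, drawn)
            qalys[s] = np.asarray(q, dtype=float)
            costs[s] = np.asarray(c, dtype=float)
    else:
        for s, child in zip(STRATEGIES, ss.spawn(len(STRATEGIES))):
            drawn = sample_parameters(params, np.random.default_rng(child), size=n_iterations)
            q, c = _arm_qaly_cost(s, drawn)
            qalys[s] = np.asarray(q, dtype=float)
            costs[s] = np.asarray(c, dtype=float)
    seed_label = seed if isinstance(seed, int) else None
    draws = PsaDraws(
        n_iterations=n_iterations,
        seed=seed_label,
        qalys=pd.DataFrame(qalys, columns=list(STRATEGIES)),
        costs=pd.DataFrame(costs, columns=list(STRATEGIES)),
    )
    draws.validate()
    return draws


def _win_weights(nmb: np.ndarray) -> np.ndarray:
    """Per-iteration winner indicators; exact NMB ties split equally."""
    best = nmb.max(axis=1, keepdims=True)
    mask = nmb == best
    return mask / mask.sum(axis=1, keepdims=True)


def ceac(draws: PsaDraws, lambda_grid=DEFAULT_LAMBDA_GRID) -> CeacTable:
    """Cost-effectiveness acceptability curve over ``lambda_grid``."""
    lambdas = np.asarray(list(lambda_grid), dtype=float)
    if lambdas.size == 0:
        raise ValueError("lambda grid is empty")
    if (lambdas < 0).any():
        raise ValueError("willingness-to-pay must be >= 0")
    q = draws.qalys.to_numpy()
    c = draws.costs.to_numpy()
    probs = np.empty((lambdas.size, len(STRATEGIES)))
    for i, lam in enumerate(lambdas):
        probs[i] = _win_weights(lam * q - c).mean(axis=0)
    table = CeacTable(
        lambdas=lambdas,
        probabilities=pd.DataFrame(probs, columns=list(STRATEGIES)),
    )
    table.validate()
    return table


def ce_plane(draws: PsaDraws, reference: str) -> pd.DataFrame:
    """Incremental (ΔQALY, ΔCost) scatter versus ``reference``, per iteration."""
    if reference not in STRATEGIES:
        raise KeyError(f"unknown reference strategy: {reference!r}")
    rows = []
    for s in STRATEGIES:
        if s == reference:
            continue
        rows.append(
            pd.DataFrame(
                {
                    "iteration": np.arange(draws.n_iterations),
                    "strategy": s,
                    "delta_qaly": (draws.qalys[s] - draws.qalys[reference]).to_numpy(),
                    "delta_cost": (draws.costs[s] - draws.costs[reference]).to_numpy(),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def convergence_check(draws: PsaDraws, wtp: float, block_count: int = 10) -> float:
    """Largest CEAC probability change between the final two cumulative blocks.

    The CEAC at ``wtp`` is recomputed at ``block_count`` cumulative
    iteration counts; the return value is the maximum absolute change in
    any arm's probability between the last two, a simple stopping
    diagnostic for the number of Monte Carlo iterations.
    """
    if block_count < 2:
        raise ValueError("block_count must be >= 2")
    q = draws.qalys.to_numpy()
    c = draws.costs.to_numpy()
    weights = _win_weights(wtp * q - c)
    edges = np.linspace(0, draws.n_iterations, block_count + 1).astype(int)[1:]
    cumulative = [weights[:n].mean(axis=0) for n in edges]
    return float(np.abs(cumulative[-1] - cumulative[-2]).max())
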