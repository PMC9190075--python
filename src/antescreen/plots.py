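"""Optional graphical outputs: CEAC line plots and cost-effectiveness planes.

CSV tables are the contract of the command-line interface; these plots
are convenience artifacts layered on top of them.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

__all__ = ["plot_ceac", "plot_ce_plane"]

_LABELS = {
    "whooley": "Whooley",
    "epds": "EPDS",
    "whooley_epds": "Whooley-EPDS",
    "no_screen": "No screen",
}


def plot_ceac(ceac_table, ax=None):
    """Probability cost-effective against willingness to pay, one line per arm."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    for strategy in ceac_table.probabilities.columns:
        ax.plot(
            ceac_table.lambdas,
            ceac_table.probabilities[strategy],
            label=_LABELS.get(strategy, strategy),
        )
    ax.set_xlabel("Willingness to pay (£ per QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0, 1)
    ax.legend()
    return ax


def plot_ce_plane(plane, ax=None):
    """Incremental cost against incremental QALYs, one scatter per arm."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    for strategy, group in plane.groupby("strategy"):
        ax.scatter(
            group["delta_qaly"],
            group["delta_cost"],
            s=4,
            alpha=0.4,
            label=_LABELS.get(strategy, strategy),
        )
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (£)")
    ax.legend()
    return ax
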