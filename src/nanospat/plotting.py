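"""Presentation-style plots: standardized curves with the significance line
at 1, and bar summaries (L_max / LBI / density) with SEM error bars.

Plotting is side-effect-only; nothing here feeds back into the statistics.
"""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

from .inference import GroupSummary
from .patterns import RadialCurve
from .states import StateDistribution

__all__ = ["plot_standardized", "plot_group_bars", "plot_state_fractions"]


def plot_standardized(
    curves: Sequence[RadialCurve],
    labels: Sequence[str] | None = None,
    ax=None,
    significance_line: float = 1.0,
):
    """Standardized L(r)-r curves versus radius with the C.I. line at 1."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    for i, c in enumerate(curves):
        label = labels[i] if labels else None
        ax.plot(c.radii, c.values, lw=1.2, label=label)
    ax.axhline(significance_line, color="k", ls="--", lw=0.8)
    ax.set_xlabel("r (nm)")
    ax.set_ylabel("Std L(r) - r")
    if labels:
        ax.legend(frameon=False, fontsize=8)
    return ax


def plot_group_bars(
    summaries: Sequence[GroupSummary],
    ax=None,
    ylabel: str = "",
    reference: float | None = None,
):
    """Bar chart of group means with SEM error bars.

    ``reference`` draws a dashed guide (e.g. 100 for the LBI co-localization
    threshold, 1 for L_max significance).
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3.5))
    xs = range(len(summaries))
    ax.bar(
        xs,
        [s.mean for s in summaries],
        yerr=[s.sem for s in summaries],
        capsize=3,
        color="0.7",
        edgecolor="k",
    )
    ax.set_xticks(list(xs))
    ax.set_xticklabels([s.condition for s in summaries], rotation=30, ha="right")
    if reference is not None:
        ax.axhline(reference, color="k", ls="--", lw=0.8)
    ax.set_ylabel(ylabel)
    return ax


def plot_state_fractions(dists: Sequence[StateDistribution], ax=None):
    """Stacked monomer/dimer/oligomer fractions per sheet."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    xs = range(len(dists))
    mono = [d.monomer for d in dists]
    dim = [d.dimer for d in dists]
    olig = [d.oligomer for d in dists]
    ax.bar(xs, mono, label="monomer", color="0.85", edgecolor="k")
    ax.bar(xs, dim, bottom=mono, label="dimer", color="0.6", edgecolor="k")
    ax.bar(
        xs,
        olig,
        bottom=[m + d for m, d in zip(mono, dim)],
        label="oligomer",
        color="0.3",
        edgecolor="k",
    )
    ax.set_xticks(list(xs))
    ax.set_xticklabels([d.sheet_id for d in dists], rotation=30, ha="right")
    ax.set_ylabel("fraction of particles")
    ax.legend(frameon=False, fontsize=8)
    return ax
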