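"""Small figure helpers: HDR contour + marginals, stacked mode proportions."""

from __future__ import annotations

import numpy as np

from .clustering import TAGS, BootstrapResult, ContourSet


def plot_contours(cs: ContourSet, ax=None):
    """Contour plot of the (q, a) mass with 1D marginals top and right.

    Returns the matplotlib figure.  Contour lines are drawn at the HDR mass
    thresholds (50/80/95% by default), innermost first.
    """
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(6, 6))
    gs = fig.add_gridspec(2, 2, width_ratios=(4, 1), height_ratios=(1, 4),
                          hspace=0.05, wspace=0.05)
    ax_main = fig.add_subplot(gs[1, 0])
    ax_top = fig.add_subplot(gs[0, 0], sharex=ax_main)
    ax_right = fig.add_subplot(gs[1, 1], sharey=ax_main)

    qc = 0.5 * (cs.q_edges[:-1] + cs.q_edges[1:])
    ac = 0.5 * (cs.a_edges[:-1] + cs.a_edges[1:])
    levels = sorted(cs.thresholds.values())
    ax_main.contourf(qc, ac, cs.mass.T, levels=[*levels, cs.mass.max() + 1e-12],
                     cmap="viridis", alpha=0.8)
    ax_main.contour(qc, ac, cs.mass.T, levels=levels, colors="k", linewidths=0.8)
    ax_main.set_xlabel("persistence q")
    ax_main.set_ylabel("activity a (µm/min)")
    ax_top.bar(qc, cs.marginal_q, width=np.diff(cs.q_edges), color="grey")
    ax_top.tick_params(labelbottom=False)
    ax_right.barh(ac, cs.marginal_a, height=np.diff(cs.a_edges), color="grey")
    ax_right.tick_params(labelleft=False)
    return fig


def plot_proportions(results: dict[str, BootstrapResult]):
    """Stacked bars of bootstrap mean mode proportions per condition,
    with SD whiskers on the cumulative sums."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 * max(len(results), 2) + 1, 4))
    conditions = list(results)
    bottoms = np.zeros(len(conditions))
    colors = {TAGS[0]: "#d62728", TAGS[1]: "#ff9f40", TAGS[2]: "#4878cf"}
    for tag in TAGS:
        heights = [results[c].mean_proportions[tag] for c in conditions]
        errs = [results[c].sd_cumulative[tag] for c in conditions]
        ax.bar(conditions, heights, bottom=bottoms, label=tag, color=colors[tag])
        ax.errorbar(conditions, bottoms + heights, yerr=errs, fmt="none",
                    ecolor="k", capsize=3)
        bottoms += heights
    ax.set_ylabel("proportion of cells")
    ax.set_ylim(0, 1.05)
    ax.legend()
    return fig
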