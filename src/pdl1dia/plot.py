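"""Plots for paired-score agreement and synthetic cores."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .concordance import PairedScores


def plot_concordance(pairs: PairedScores, ax=None, flagged: dict | None = None):
    """Scatter of paired scores, concordant pairs green, discordant red.

    ``flagged`` core_ids (manual-review pass-through) are drawn blue.
    Returns the matplotlib axes.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    f = pairs.evaluable()
    conc = (f["category_a"] == f["category_b"]).to_numpy()
    flag = f["core_id"].isin(flagged or {}).to_numpy()
    for sel, colour, label in (
        (conc & ~flag, "tab:green", "concordant"),
        (~conc & ~flag, "tab:red", "discordant"),
        (flag, "tab:blue", "flagged for review"),
    ):
        if sel.any():
            ax.scatter(f.loc[sel, "score_a"], f.loc[sel, "score_b"],
                       s=18, c=colour, label=label, alpha=0.8)
    for cut in (1, 50):
        ax.axvline(cut, color="grey", lw=0.6, ls=":")
        ax.axhline(cut, color="grey", lw=0.6, ls=":")
    ax.plot([0, 100], [0, 100], color="grey", lw=0.8)
    ax.set_xlabel(f"TPS, {pairs.label_a} (%)")
    ax.set_ylabel(f"TPS, {pairs.label_b} (%)")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_core(stack, truth=None, ax=None):
    """False-colour composite of a channel stack (DAPI blue, CK green,
    PD-L1 red), with nest outlines if ground truth is given."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    rgb = np.stack([
        stack.channels["PDL1"], stack.channels["CK"], stack.channels["DAPI"]
    ], axis=-1)
    ax.imshow(np.clip(rgb, 0, 1))
    if truth is not None:
        for verts in truth.nests:
            closed = np.vstack([verts, verts[:1]])
            ax.plot(closed[:, 0], closed[:, 1], color="white", lw=0.8)
    ax.set_axis_off()
    return ax
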