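"""Plotting helpers for evaluation results."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers may switch backends first
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["accuracy_boxplot"]


def accuracy_boxplot(table: pd.DataFrame, ax=None, title: str = ""):
    """Per-fold accuracy distributions over stimulation length, one box
    group per prediction rule.

    Expects the tidy table produced by cross-validation (columns ``rule``,
    ``length``, ``accuracy``).
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    rules = list(dict.fromkeys(table.rule))
    lengths = sorted(table.length.unique())
    width = 0.8 / len(rules)
    for j, rule in enumerate(rules):
        sub = table[table.rule == rule]
        data = [sub[sub.length == l].accuracy.to_numpy() for l in lengths]
        pos = [i + (j - (len(rules) - 1) / 2) * width for i in range(len(lengths))]
        bp = ax.boxplot(data, positions=pos, widths=width * 0.9,
                        patch_artist=True, manage_ticks=False)
        color = plt.get_cmap("tab10")(j)
        for box in bp["boxes"]:
            box.set_facecolor(color)
            box.set_alpha(0.6)
        ax.plot([], [], color=color, label=rule)
    ax.set_xticks(range(len(lengths)))
    ax.set_xticklabels([f"{l:g}" for l in lengths])
    ax.set_xlabel("stimulation length")
    ax.set_ylabel("accuracy")
    ax.set_ylim(0, 1.02)
    ax.legend(loc="lower right", title="rule")
    if title:
        ax.set_title(title)
    return ax
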