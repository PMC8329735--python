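"""Minimal figures: group identification and discrimination curves.

Numeric tables are the primary interface; these plots are a visual
check that the boundary aligns with the discrimination peak.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .identification import tabulate_identification

__all__ = ["plot_experiment"]


def plot_experiment(
    responses: pd.DataFrame,
    unit_table: pd.DataFrame,
    experiment: str,
    out_path,
) -> Path:
    """Two panels per group: mean identification curve (proportion cat2
    by stimulus) and mean discrimination score by comparison unit."""
    ident = responses[
        (responses["task"] == "identification") & (responses["experiment"] == experiment)
    ]
    groups = sorted(ident["group"].unique())
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))

    for group in groups:
        sub = ident[ident["group"] == group]
        curves = []
        for _, one in sub.groupby("listener_id"):
            t = tabulate_identification(one)
            curves.append(t["prop_cat2"])
        mean_curve = pd.concat(curves, axis=1).mean(axis=1)
        axes[0].plot(mean_curve.index, mean_curve.values, marker="o", label=group)

        u = unit_table[unit_table["group"] == group]
        agg = u.groupby("unit", sort=False)["score"].mean()
        order = sorted(agg.index, key=lambda s: int(s.split("-")[0]))
        mids = [np.mean([int(v) for v in lab.split("-")]) for lab in order]
        axes[1].plot(mids, agg.loc[order].values, marker="s", label=group)

    axes[0].set_xlabel("stimulus index")
    axes[0].set_ylabel("P(category 2)")
    axes[0].set_title(f"{experiment}: identification")
    axes[0].axhline(0.5, color="grey", lw=0.5)
    axes[1].set_xlabel("unit midpoint")
    axes[1].set_ylabel("discrimination score P")
    axes[1].set_title(f"{experiment}: discrimination")
    axes[1].axhline(0.5, color="grey", lw=0.5)
    axes[1].legend(fontsize=7)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
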