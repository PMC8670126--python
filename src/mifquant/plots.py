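"""Box-plot style outputs for group comparisons of section-level scores."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["marker_boxplot"]


def marker_boxplot(
    sections: pd.DataFrame,
    marker: str,
    compartment: str,
    path: str | Path,
    *,
    group_col: str = "group",
    score_col: str = "median_score",
) -> Path:
    """Per-group box plot of one marker/compartment's section medians.

    Boxes show the median and IQR with individual sections overlaid, the
    standard display for section-level QIF comparisons.
    """
    sub = sections[
        (sections["marker"] == marker) & (sections["compartment"] == compartment)
    ]
    groups = list(pd.unique(sub[group_col]))
    data = [sub.loc[sub[group_col] == g, score_col].dropna() for g in groups]
    fig, ax = plt.subplots(figsize=(3.2, 3.6))
    ax.boxplot(data, tick_labels=groups, showfliers=False)
    for i, vals in enumerate(data, start=1):
        ax.plot([i] * len(vals), vals, "o", ms=3, alpha=0.6, color="0.3")
    ax.set_ylabel(f"{marker} QIF score ({compartment})")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
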