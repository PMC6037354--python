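"""Quick-look plots: incidence tracks and per-category count bars."""

from __future__ import annotations

import numpy as np

from .detection import CATEGORY_LABELS, IncidenceTrack


def plot_incidence(track: IncidenceTrack, ax=None):
    """ROH incidence along the genome, chromosomes concatenated."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(12, 3))
    f = track.frame()
    offset = 0
    ticks, labels = [], []
    for chrom in track.map.chromosomes:
        sub = f[f["chrom"] == chrom]
        x = sub["pos"].to_numpy() + offset
        ax.plot(x, sub["count"].to_numpy(), lw=0.6)
        ticks.append(offset + sub["pos"].max() / 2)
        labels.append(chrom)
        offset += sub["pos"].max()
    ax.set_xticks(ticks, labels, fontsize=7)
    ax.set_ylabel("individuals with ROH")
    return ax


def plot_category_counts(table, ax=None):
    """Grouped bar chart of mean per-individual ROH counts by category,
    from `category_count_table` output."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    cats = [r for r in table["category"] if r in CATEGORY_LABELS]
    sub = table[table["category"].isin(cats)]
    mean_cols = [c for c in sub.columns if c.startswith("mean_")]
    x = np.arange(len(cats))
    width = 0.8 / len(mean_cols)
    for k, col in enumerate(mean_cols):
        sem_col = col.replace("mean_", "sem_")
        ax.bar(x + k * width, sub[col], width,
               yerr=sub[sem_col], label=col.removeprefix("mean_"), capsize=2)
    ax.set_xticks(x + width / 2, cats, rotation=30)
    ax.set_ylabel("mean ROH per individual")
    ax.legend()
    return ax
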