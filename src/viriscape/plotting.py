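"""Basic plot helpers: stacked divergence landscapes and window densities."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def plot_landscape(landscape, ax=None, title=None):
    """Stacked bar chart of a divergence-landscape matrix (bin x subclass)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    bottom = None
    for subclass in landscape.columns:
        vals = landscape[subclass].to_numpy()
        ax.bar(landscape.index, vals, width=0.9, bottom=bottom, label=subclass)
        bottom = vals if bottom is None else bottom + vals
    ax.set_xlabel("% divergence from consensus")
    ax.set_ylabel("genome proportion")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    return ax


def plot_window_density(density, chrom, ax=None):
    """Per-window repeat density along one chromosome, one line per subclass."""
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    sub = density[density["chrom"] == chrom]
    for subclass, grp in sub.groupby("subclass"):
        ax.plot(grp["start"], grp["bp"], label=subclass, lw=1)
    ax.set_xlabel(f"{chrom} position (bp)")
    ax.set_ylabel("repeat bp / window")
    ax.legend(fontsize=8)
    return ax
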