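"""Convenience Manhattan and scree plots for scan outputs."""

from __future__ import annotations

import numpy as np


def manhattan(table, value_col: str, ax=None, threshold: float | None = None,
              abs_values: bool = False):
    """Manhattan-style plot of a per-SNP scan track.

    ``table`` needs chrom/pos columns plus ``value_col``; chromosomes are
    laid out consecutively with alternating shades.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    offset = 0
    ticks, labels = [], []
    for i, (chrom, grp) in enumerate(table.groupby("chrom", sort=False)):
        x = grp["pos"].to_numpy() + offset
        y = grp[value_col].to_numpy()
        if abs_values:
            y = np.abs(y)
        ax.scatter(x, y, s=4, color=("0.35", "0.65")[i % 2], rasterized=True)
        ticks.append(offset + grp["pos"].mean())
        labels.append(str(chrom))
        offset += grp["pos"].max() + 1
    if threshold is not None:
        ax.axhline(threshold, ls="--", color="firebrick", lw=1)
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(value_col)
    return ax


def scree(variance_ratio, ax=None):
    """Scree plot of PCA variance proportions."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    k = np.arange(1, len(variance_ratio) + 1)
    ax.plot(k, variance_ratio, "o-")
    ax.set_xlabel("principal component")
    ax.set_ylabel("proportion of variance")
    return ax
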