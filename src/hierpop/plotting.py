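"""Small matplotlib helpers for the standard figures of the workflow."""
from __future__ import annotations

import numpy as np
import pandas as pd


def plot_pa_by_level(summary: pd.DataFrame, ax=None):
    """Bar chart of predictive ability per hierarchical level with SE bars.

    ``summary`` is a CvResult.summary() frame (index: level; columns mean, se).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.bar(summary.index, summary["mean"], yerr=summary["se"], color="#4878b0", capsize=3)
    ax.set_ylabel("predictive ability (r)")
    ax.axhline(0, color="k", lw=0.5)
    return ax


def plot_ld_curve(curve: pd.DataFrame, threshold: float = 0.2, ax=None):
    """Mean r^2 per distance class with the extent threshold marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve["midpoint"] / 1000.0, curve["mean_r2"], marker="o", ms=3)
    ax.axhline(threshold, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("distance (kb)")
    ax.set_ylabel("mean $r^2$")
    return ax


def manhattan(scan_table: pd.DataFrame, threshold: float | None = None, ax=None):
    """-log10 p against position, one color block per chromosome."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    offset = 0
    for i, (chrom, sub) in enumerate(scan_table.groupby("chrom", sort=False)):
        ok = sub["p"].notna()
        ax.scatter(
            offset + sub.loc[ok, "pos"], -np.log10(sub.loc[ok, "p"]),
            s=4, color=["#4878b0", "#e1812c"][i % 2], rasterized=True,
        )
        offset += sub["pos"].max()
    if threshold is not None:
        ax.axhline(-np.log10(threshold), color="red", lw=0.8)
    ax.set_xlabel("position")
    ax.set_ylabel("$-\\log_{10} p$")
    return ax
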