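"""Genome-wide CAAFD profile figure."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .scan import RegionCall

__all__ = ["plot_profile"]


def plot_profile(
    scores: pd.DataFrame,
    path: str | Path,
    region: RegionCall | None = None,
) -> None:
    """One panel per chromosome: window center (Mb) vs CAAFD.

    The called target region, if given, is shaded on its chromosome.
    """
    if len(scores) == 0:
        raise ValueError("cannot plot an empty scan")
    chroms = list(pd.unique(scores["chrom"]))
    fig, axes = plt.subplots(
        1, len(chroms), figsize=(3.0 * len(chroms), 3.2),
        sharey=True, squeeze=False,
    )
    ymax = max(1.05 * scores["caafd"].abs().max(), 0.05)
    for ax, chrom in zip(axes[0], chroms):
        sub = scores[scores["chrom"] == chrom]
        ax.plot(sub["center"] / 1e6, sub["caafd"], lw=0.8, color="tab:blue")
        ax.axhline(0.0, color="grey", lw=0.5)
        if region is not None and region.chrom == chrom:
            ax.axvspan(region.start / 1e6, region.end / 1e6,
                       color="tab:orange", alpha=0.25, lw=0)
            ax.axvline(region.peak_center / 1e6, color="tab:red", lw=0.8, ls="--")
        ax.set_title(str(chrom))
        ax.set_xlabel("position (Mb)")
        ax.set_ylim(-ymax, ymax)
    axes[0][0].set_ylabel("CAAFD")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
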