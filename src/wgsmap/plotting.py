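"""Mapping plots: per-chromosome SNP-fraction scatter with LOESS overlay."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .mapping import FrequencySeries, LoessCurve, MappingInterval

__all__ = ["plot_frequency_map"]


def plot_frequency_map(series: FrequencySeries, curve: LoessCurve | None = None,
                       intervals: list[MappingInterval] | None = None,
                       truth: list[tuple[str, int]] | None = None,
                       path=None, title: str | None = None):
    """One panel per chromosome: observed fractions, smoothed curve,
    shaded mapping interval(s), and (optionally) the true locus."""
    chroms = list(series.lengths)
    fig, axes = plt.subplots(len(chroms), 1, figsize=(9, 2.2 * len(chroms)),
                             squeeze=False, sharey=True)
    for ax, chrom in zip(axes[:, 0], chroms):
        sub = series.on(chrom)
        ax.scatter(sub["position"] / 1e6, sub["frequency"], s=4,
                   color="0.4", alpha=0.5, linewidths=0)
        if curve is not None and chrom in curve.grids:
            grid, vals = curve.on(chrom)
            ax.plot(grid / 1e6, vals, color="forestgreen", lw=1.5)
        for iv in intervals or []:
            if iv.chromosome == chrom:
                ax.axvspan(iv.start / 1e6, iv.end / 1e6, color="firebrick",
                           alpha=0.15)
        for tc, tp in truth or []:
            if tc == chrom:
                ax.axvline(tp / 1e6, color="firebrick", ls="--", lw=1)
        ax.set_xlim(0, series.lengths[chrom] / 1e6)
        ax.set_ylim(-0.02, 1.02)
        ax.set_ylabel("fraction")
        ax.set_title(chrom, loc="left", fontsize=9)
    axes[-1, 0].set_xlabel("position (Mbp)")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
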