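"""Three-track scan plots: bulk SNP-indices and delta index per chromosome."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .window_scan import CandidateRegion, ScanConfig, WindowStat

__all__ = ["plot_scan"]


def plot_scan(
    stats: Sequence[WindowStat],
    regions: Sequence[CandidateRegion],
    chrom: str,
    chrom_length: int,
    outpath,
    scan_config: ScanConfig | None = None,
) -> None:
    """Write a PNG with green-bulk index, yellow-bulk index and delta tracks.

    Candidate regions are shaded on every track.
    """
    scan_config = scan_config or ScanConfig()
    mid = [(w.start + w.end) / 2e6 for w in stats if w.n_snps > 0]
    green = [w.mean_index_green for w in stats if w.n_snps > 0]
    yellow = [w.mean_index_yellow for w in stats if w.n_snps > 0]
    delta = [w.mean_delta for w in stats if w.n_snps > 0]

    fig, axes = plt.subplots(3, 1, figsize=(10, 7), sharex=True)
    tracks = [
        (green, "GC-bulk SNP-index", "green", (0, 1)),
        (yellow, "YC-bulk SNP-index", "goldenrod", (0, 1)),
        (delta, "Δ(SNP-index)", "steelblue", (-1, 1)),
    ]
    for ax, (values, label, color, ylim) in zip(axes, tracks):
        ax.plot(mid, values, color=color, lw=0.8)
        ax.set_ylabel(label, fontsize=9)
        ax.set_ylim(*ylim)
        for region in regions:
            ax.axvspan(region.start / 1e6, region.end / 1e6, color="gold", alpha=0.3)
    axes[0].axhline(scan_config.index_threshold, color="gray", ls="--", lw=0.6)
    axes[2].axhline(0.0, color="gray", lw=0.6)
    axes[2].set_xlabel(f"{chrom} position (Mb)")
    axes[2].set_xlim(0, chrom_length / 1e6)
    fig.suptitle(f"Sliding-window scan: {chrom}")
    fig.tight_layout()
    fig.savefig(outpath, dpi=120)
    plt.close(fig)
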