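"""Sliding-window genome scan and candidate-region calling.

Windows are left-anchored at position 1, advanced by a fixed step and
truncated at the chromosome end.  A window qualifies when it holds
enough SNPs, its mean green-bulk SNP-index exceeds the index threshold
and its mean Fisher P falls below the P threshold; overlapping
qualifying windows are merged into candidate regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bsa_index import SnpIndexRecord

__all__ = [
    "ScanConfig",
    "WindowStat",
    "CandidateRegion",
    "make_windows",
    "window_stats",
    "call_regions",
    "write_windows_tsv",
    "write_regions_bed",
    "read_genome_table",
]


@dataclass(frozen=True)
class ScanConfig:
    window_bp: int = 2_000_000
    step_bp: int = 10_000
    index_threshold: float = 0.9
    p_threshold: float = 0.05
    min_snps_per_window: int = 10
    min_windows_per_region: int = 5
    bulk: str = "green"  # which bulk's mean index must exceed the threshold

    def __post_init__(self) -> None:
        if not self.window_bp >= self.step_bp > 0:
            raise ValueError("require window_bp >= step_bp > 0")
        for name, v in (("index_threshold", self.index_threshold),
                        ("p_threshold", self.p_threshold)):
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.bulk not in ("green", "yellow"):
            raise ValueError("bulk must be 'green' or 'yellow'")


@dataclass(frozen=True)
class WindowStat:
    chrom: str
    start: int
    end: int  # 1-based inclusive
    n_snps: int
    mean_index_green: float  # nan when empty
    mean_index_yellow: float
    mean_delta: float
    mean_p: float
    eligible: bool


@dataclass(frozen=True)
class CandidateRegion:
    chrom: str
    start: int
    end: int
    n_windows: int
    n_snps: int
    max_mean_delta: float
    min_mean_p: float


def make_windows(chrom_length: int, config: ScanConfig) -> list[tuple[int, int]]:
    """Left-anchored sliding windows over [1, chrom_length]."""
    if chrom_length < 1:
        raise ValueError("chromosome length must be >= 1")
    windows = []
    start = 1
    while start <= chrom_length:
        windows.append((start, min(start + config.window_bp - 1, chrom_length)))
        start += config.step_bp
    return windows


def window_stats(
    records: Sequence[SnpIndexRecord],
    windows: Sequence[tuple[int, int]],
    config: ScanConfig,
    chrom: str,
) -> list[WindowStat]:
    """Per-window means over the SNPs contained in each window.

    ``records`` must all belong to ``chrom`` and be sorted by position.
    Uses prefix sums so the cost is O(n + w log n).
    """
    pos = np.array([r.pos for r in records])
    if len(pos) > 1 and (np.diff(pos) < 0).any():
        raise ValueError("records must be sorted by position")
    fields = {
        "index_green": np.array([r.index_green for r in records]),
        "index_yellow": np.array([r.index_yellow for r in records]),
        "delta": np.array([r.delta for r in records]),
        "fisher_p": np.array([r.fisher_p for r in records]),
    }
    csums = {k: np.concatenate([[0.0], np.cumsum(v)]) for k, v in fields.items()}
    starts = np.array([w[0] for w in windows])
    ends = np.array([w[1] for w in windows])
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, ends, side="right")
    n = hi - lo
    out = []
    for i, (s, e) in enumerate(windows):
        k = int(n[i])
        if k > 0:
            means = {f: (csums[f][hi[i]] - csums[f][lo[i]]) / k for f in fields}
        else:
            means = {f: math.nan for f in fields}
        out.append(
            WindowStat(
                chrom=chrom,
                start=int(s),
                end=int(e),
                n_snps=k,
                mean_index_green=means["index_green"],
                mean_index_yellow=means["index_yellow"],
                mean_delta=means["delta"],
                mean_p=means["fisher_p"],
                eligible=k >= config.min_snps_per_window,
            )
        )
    return out


def _qualifies(w: WindowStat, config: ScanConfig) -> bool:
    if not w.eligible:
        return False
    mean_index = w.mean_index_green if config.bulk == "green" else w.mean_index_yellow
    return mean_index > config.index_threshold and w.mean_p < config.p_threshold


def call_regions(
    stats: Sequence[WindowStat],
    config: ScanConfig,
    records: Sequence[SnpIndexRecord] | None = None,
) -> list[CandidateRegion]:
    """Merge overlapping qualifying windows into candidate regions.

    Only groups of at least ``min_windows_per_region`` windows survive.
    If ``records`` is given, per-region SNP counts are recomputed over
    the merged span; otherwise the maximum member-window count is used.
    """
    regions: list[CandidateRegion] = []
    by_chrom: dict[str, list[WindowStat]] = {}
    for w in stats:
        if _qualifies(w, config):
            by_chrom.setdefault(w.chrom, []).append(w)
    for chrom in sorted(by_chrom):
        qualifying = sorted(by_chrom[chrom], key=lambda w: w.start)
        group: list[WindowStat] = []
        for w in qualifying + [None]:
            if group and (w is None or w.start > group[-1].end + 1):
                if len(group) >= config.min_windows_per_region:
                    start = group[0].start
                    end = max(g.end for g in group)
                    if records is not None:
                        n_snps = sum(
                            1 for r in records
                            if r.chrom == chrom and start <= r.pos <= end
                        )
                    else:
                        n_snps = max(g.n_snps for g in group)
                    regions.append(
                        CandidateRegion(
                            chrom=chrom,
                            start=start,
                            end=end,
                            n_windows=len(group),
                            n_snps=n_snps,
                            max_mean_delta=max(g.mean_delta for g in group),
                            min_mean_p=min(g.mean_p for g in group),
                        )
                    )
                group = []
            if w is not None:
                group.append(w)
    return regions


def write_windows_tsv(stats: Sequence[WindowStat], path) -> None:
    cols = [
        "chrom", "start", "end", "n_snps", "mean_index_green",
        "mean_index_yellow", "mean_delta", "mean_p", "eligible",
    ]
    df = pd.DataFrame([{c: getattr(w, c) for c in cols} for w in stats], columns=cols)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_regions_bed(regions: Sequence[CandidateRegion], path) -> None:
    """BED output (0-based half-open; internal coordinates are 1-based)."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            name = f"region_{i + 1}"
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{name}\t{r.n_snps}\t.\n")


def read_genome_table(path) -> list[tuple[str, int]]:
    """FAI-style two-column table: chromosome name, length in bp."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            out.append((parts[0], int(parts[1])))
    return out
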