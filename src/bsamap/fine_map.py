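"""Recombinant-based validation and interval refinement.

Given marker genotypes (A = yellow-parent homozygote, B = green-parent
homozygote, H = heterozygote) for segregating lines across the two
candidate regions, this module decides which locus controls each
3:1-segregating line, finds recombinant lines, and intersects their
breakpoint constraints to narrow each causal-locus interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .segregation import SegClass

__all__ = [
    "MarkerGenotype",
    "LineRecord",
    "Interval",
    "RefinementError",
    "consensus_call",
    "assign_controlling_locus",
    "infer_causal_genotype",
    "find_recombinants",
    "refine_interval",
    "read_marker_tsv",
]

CALL_A = "A"
CALL_B = "B"
CALL_H = "H"
CALL_MISSING = "."
_VALID_CALLS = {CALL_A, CALL_B, CALL_H, CALL_MISSING}


@dataclass(frozen=True)
class MarkerGenotype:
    marker_id: str
    chrom: str
    pos: int
    call: str

    def __post_init__(self) -> None:
        if self.call not in _VALID_CALLS:
            raise ValueError(f"invalid marker call {self.call!r}")


@dataclass
class LineRecord:
    """One progeny line: segregation class plus marker calls per region."""

    line_id: str
    seg_class: SegClass | None = None
    region_calls: dict[str, list[MarkerGenotype]] = field(default_factory=dict)
    inferred_genotype: dict[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class Interval:
    chrom: str
    left: int
    right: int  # 1-based inclusive bounds

    def __post_init__(self) -> None:
        if self.left > self.right:
            raise ValueError("left bound exceeds right bound")

    @property
    def width(self) -> int:
        return self.right - self.left + 1

    def contains(self, pos: int) -> bool:
        return self.left <= pos <= self.right


class RefinementError(ValueError):
    """Raised when recombinant constraints are mutually exclusive."""


def _sorted_calls(calls: Sequence[MarkerGenotype]) -> list[MarkerGenotype]:
    out = sorted(calls, key=lambda m: m.pos)
    positions = [m.pos for m in out]
    if len(set(positions)) != len(positions):
        raise ValueError("duplicate marker positions within a region")
    return out


def consensus_call(calls: Sequence[MarkerGenotype]) -> str:
    """Majority genotype over non-missing markers; ties break to 'unknown'."""
    counts: dict[str, int] = {}
    for m in calls:
        if m.call != CALL_MISSING:
            counts[m.call] = counts.get(m.call, 0) + 1
    if not counts:
        return "unknown"
    best = max(counts.values())
    winners = [c for c, n in counts.items() if n == best]
    return winners[0] if len(winners) == 1 else "unknown"


def assign_controlling_locus(
    line: LineRecord, region1: str = "locus1", region2: str = "locus2"
) -> str:
    """Which locus segregates in a 3:1 line (the other must be fixed B).

    Returns ``region1`` or ``region2``, or ``"inconsistent"`` when the
    consensus genotypes do not match the expected het-plus-recessive
    configuration.
    """
    if line.seg_class is not None and line.seg_class != SegClass.SEG_3_1:
        return "inconsistent"
    c1 = consensus_call(line.region_calls.get(region1, []))
    c2 = consensus_call(line.region_calls.get(region2, []))
    if c1 == CALL_H and c2 == CALL_B:
        return region1
    if c1 == CALL_B and c2 == CALL_H:
        return region2
    return "inconsistent"


def infer_causal_genotype(seg_class: SegClass, background_ok: bool = True) -> str:
    """Causal-locus genotype implied by a family's segregation class.

    Valid for material whose other locus is fixed homozygous recessive:
    a non-segregating-yellow family is A, a 3:1 family H, an all-green
    family B.
    """
    if not background_ok:
        return "unknown"
    mapping = {
        SegClass.ALL_RECESSIVE: CALL_B,
        SegClass.SEG_3_1: CALL_H,
        SegClass.ALL_DOMINANT: CALL_A,
    }
    return mapping.get(seg_class, "unknown")


def find_recombinants(
    lines: Mapping[str, Sequence[MarkerGenotype]],
) -> list[tuple[str, Interval]]:
    """Breakpoint intervals for lines whose calls switch within a region.

    A switch between consecutive non-missing markers at p_i < p_j places
    a crossover strictly between them, reported as the open interval
    (p_i, p_j) i.e. [p_i+1, p_j-1].
    """
    out = []
    for line_id, calls in lines.items():
        informative = [m for m in _sorted_calls(calls) if m.call != CALL_MISSING]
        for a, b in zip(informative[:-1], informative[1:]):
            if a.call != b.call:
                out.append((line_id, Interval(a.chrom, a.pos + 1, b.pos - 1)))
    return out


def _line_constraint(
    calls: Sequence[MarkerGenotype], genotype: str
) -> list[tuple[int, int]]:
    """Positions where the line's genotype can equal ``genotype``.

    The causal locus must lie in a marker run whose call matches the
    line's inferred causal genotype; each run is widened to the open
    interval bounded by the nearest mismatching markers (the crossover
    lies strictly between markers), giving a union of closed intervals.
    """
    informative = [m for m in _sorted_calls(calls) if m.call != CALL_MISSING]
    intervals: list[tuple[int, int]] = []
    i = 0
    while i < len(informative):
        if informative[i].call != genotype:
            i += 1
            continue
        j = i
        while j + 1 < len(informative) and informative[j + 1].call == genotype:
            j += 1
        left = informative[i - 1].pos + 1 if i > 0 else informative[i].pos
        right = informative[j + 1].pos - 1 if j + 1 < len(informative) else informative[j].pos
        intervals.append((left, right))
        i = j + 1
    return intervals


def _intersect(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    out = []
    for l1, r1 in a:
        for l2, r2 in b:
            lo, hi = max(l1, l2), min(r1, r2)
            if lo <= hi:
                out.append((lo, hi))
    return sorted(out)


def refine_interval(
    lines: Sequence[tuple[str, Sequence[MarkerGenotype], str]],
) -> Interval:
    """Intersect per-line locus constraints into one refined interval.

    ``lines`` holds (line_id, ordered marker calls, inferred causal
    genotype) triples; lines with unknown genotype are skipped.  The
    returned interval spans the intersection of all constraints (if the
    intersection is a union of disjoint pieces, their spanning interval
    is returned, which is conservative but always contains the locus).
    Mutually exclusive constraints raise :class:`RefinementError` naming
    the offending line.
    """
    constraint: list[tuple[int, int]] | None = None
    chrom = None
    used = []
    for line_id, calls, genotype in lines:
        if genotype not in (CALL_A, CALL_B, CALL_H):
            continue
        calls = list(calls)
        if not calls:
            continue
        chrom = calls[0].chrom
        this = _line_constraint(calls, genotype)
        if not this:
            raise RefinementError(
                f"line {line_id}: no marker matches its inferred genotype {genotype}"
            )
        if constraint is None:
            constraint = this
        else:
            constraint = _intersect(constraint, this)
            if not constraint:
                raise RefinementError(
                    f"line {line_id} contradicts lines {', '.join(used)}: "
                    "empty breakpoint intersection (suspect genotyping or "
                    "phenotyping error)"
                )
        used.append(line_id)
    if constraint is None:
        raise ValueError("no informative line provided")
    return Interval(chrom, constraint[0][0], constraint[-1][1])


def read_marker_tsv(path) -> dict[str, list[MarkerGenotype]]:
    """line_id -> position-sorted marker calls (columns: line_id,
    marker_id, chrom, pos, call)."""
    df = pd.read_csv(path, sep="\t", dtype={"line_id": str, "call": str})
    out: dict[str, list[MarkerGenotype]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.line_id), []).append(
            MarkerGenotype(str(r.marker_id), str(r.chrom), int(r.pos), str(r.call))
        )
    for line_id in out:
        out[line_id] = sorted(out[line_id], key=lambda m: (m.chrom, m.pos))
    return out
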