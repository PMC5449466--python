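"""Mendelian segregation statistics.

Goodness-of-fit chi-square tests for arbitrary two-class segregation
ratios (with and without Yates continuity correction), classification of
selfed-progeny families into segregation classes, and the four-class
duplicate-dominant (7:4:4:1) model test.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SegCounts",
    "ChiSquareResult",
    "SegClass",
    "chi2_gof",
    "classify_f3",
    "classify_f3_table",
    "two_gene_model_test",
    "read_phenotype_tsv",
    "write_phenotype_tsv",
]


@dataclass(frozen=True)
class SegCounts:
    """Observed two-class phenotype counts for one line or population."""

    n_yellow: int
    n_green: int
    line_id: str | None = None

    def __post_init__(self) -> None:
        if self.n_yellow < 0 or self.n_green < 0:
            raise ValueError("counts must be non-negative")
        if self.n_yellow + self.n_green < 1:
            raise ValueError("at least one seed required")

    @property
    def total(self) -> int:
        return self.n_yellow + self.n_green


@dataclass(frozen=True)
class ChiSquareResult:
    """Both the continuity-corrected and uncorrected 1-df statistics.

    ``chi2_corrected`` applies the classic Yates correction
    ``sum((|O-E| - 0.5)^2 / E)`` without flooring the adjusted deviation
    at zero; for near-perfect fits (|O-E| < 0.25 per cell) the corrected
    statistic can therefore exceed the uncorrected one.
    """

    chi2_corrected: float
    chi2_uncorrected: float
    df: int
    p_corrected: float
    p_uncorrected: float
    expected: tuple[float, ...]
    ratio: tuple[float, ...]


class SegClass(enum.Enum):
    """Segregation class of a selfed F2:3 family."""

    ALL_DOMINANT = "all_dominant"
    SEG_3_1 = "seg_3_1"
    SEG_15_1 = "seg_15_1"
    ALL_RECESSIVE = "all_recessive"
    AMBIGUOUS = "ambiguous"


def _gof_statistics(observed, expected, correction: bool, floor_at_zero: bool):
    observed = np.asarray(observed, dtype=float)
    dev = np.abs(observed - expected)
    if correction:
        dev = dev - 0.5
        if floor_at_zero:
            dev = np.maximum(dev, 0.0)
    return (dev**2 / expected).sum(axis=-1)


def chi2_gof(
    counts: SegCounts,
    ratio: tuple[float, float] = (15, 1),
    *,
    floor_at_zero: bool = False,
) -> ChiSquareResult:
    """Goodness-of-fit chi-square of observed counts against ``a:b``.

    Returns both the Yates-corrected and uncorrected statistic with
    their 1-df upper-tail P-values.  The correction subtracts 0.5 from
    each absolute deviation; set ``floor_at_zero=True`` to clip the
    adjusted deviation at 0 (some textbooks' variant).
    """
    a, b = ratio
    if a <= 0 or b <= 0:
        raise ValueError("ratio components must be positive")
    n = counts.total
    expected = np.array([n * a / (a + b), n * b / (a + b)])
    observed = np.array([counts.n_yellow, counts.n_green], dtype=float)
    chi_u = float(_gof_statistics(observed, expected, False, floor_at_zero))
    chi_c = float(_gof_statistics(observed, expected, True, floor_at_zero))
    return ChiSquareResult(
        chi2_corrected=chi_c,
        chi2_uncorrected=chi_u,
        df=1,
        p_corrected=float(stats.chi2.sf(chi_c, 1)),
        p_uncorrected=float(stats.chi2.sf(chi_u, 1)),
        expected=tuple(expected),
        ratio=(float(a), float(b)),
    )


# Yellow:green expectations tested when a family segregates.
_SEG_RATIOS = {SegClass.SEG_3_1: (3.0, 1.0), SegClass.SEG_15_1: (15.0, 1.0)}


def classify_f3(counts: SegCounts, alpha: float = 0.05) -> SegClass:
    """Classify one F2:3 family by its yellow/green seed counts.

    Non-segregating families are assigned directly; segregating ones are
    tested against 3:1 and 15:1 with the corrected chi-square.  If both
    ratios fit at ``alpha`` the smaller statistic wins; if neither fits
    the family is ambiguous.
    """
    if counts.n_green == 0:
        return SegClass.ALL_DOMINANT
    if counts.n_yellow == 0:
        return SegClass.ALL_RECESSIVE
    crit = stats.chi2.isf(alpha, 1)
    fits: dict[SegClass, float] = {}
    for cls, ratio in _SEG_RATIOS.items():
        chi_c = chi2_gof(counts, ratio).chi2_corrected
        if chi_c <= crit:
            fits[cls] = chi_c
    if not fits:
        return SegClass.AMBIGUOUS
    return min(fits, key=fits.get)


def classify_f3_table(
    n_yellow: Sequence[int], n_green: Sequence[int], alpha: float = 0.05
) -> np.ndarray:
    """Vectorized :func:`classify_f3` over parallel count arrays."""
    ny = np.asarray(n_yellow, dtype=float)
    ng = np.asarray(n_green, dtype=float)
    n = ny + ng
    crit = stats.chi2.isf(alpha, 1)
    out = np.full(ny.shape, SegClass.AMBIGUOUS, dtype=object)

    chis = {}
    for cls, (a, b) in _SEG_RATIOS.items():
        exp = np.stack([n * a / (a + b), n * b / (a + b)], axis=-1)
        obs = np.stack([ny, ng], axis=-1)
        chis[cls] = _gof_statistics(obs, exp, True, False)
    fit31 = chis[SegClass.SEG_3_1] <= crit
    fit151 = chis[SegClass.SEG_15_1] <= crit
    out[fit151] = SegClass.SEG_15_1
    out[fit31] = SegClass.SEG_3_1
    both = fit31 & fit151
    out[both & (chis[SegClass.SEG_15_1] < chis[SegClass.SEG_3_1])] = SegClass.SEG_15_1
    out[ng == 0] = SegClass.ALL_DOMINANT
    out[ny == 0] = SegClass.ALL_RECESSIVE
    return out


def two_gene_model_test(class_counts: Sequence[int]) -> ChiSquareResult:
    """Test four F2:3 class counts against the 7:4:4:1 expectation.

    ``class_counts`` must be ordered (all_dominant, 3:1, 15:1,
    all_recessive).  Uses the uncorrected statistic with 3 df; the
    corrected variant is reported for completeness.
    """
    observed = np.asarray(class_counts, dtype=float)
    if observed.shape != (4,):
        raise ValueError("exactly four class counts required")
    if (observed < 0).any():
        raise ValueError("counts must be non-negative")
    n = observed.sum()
    ratio = np.array([7.0, 4.0, 4.0, 1.0])
    expected = n * ratio / ratio.sum()
    if (expected < 1).any():
        warnings.warn("expected class count below 1; chi-square unreliable")
    chi_u = float(_gof_statistics(observed, expected, False, False))
    chi_c = float(_gof_statistics(observed, expected, True, False))
    return ChiSquareResult(
        chi2_corrected=chi_c,
        chi2_uncorrected=chi_u,
        df=3,
        p_corrected=float(stats.chi2.sf(chi_c, 3)),
        p_uncorrected=float(stats.chi2.sf(chi_u, 3)),
        expected=tuple(expected),
        ratio=tuple(ratio),
    )


def read_phenotype_tsv(path) -> list[SegCounts]:
    df = pd.read_csv(path, sep="\t", dtype={"line_id": str})
    return [
        SegCounts(int(r.n_yellow), int(r.n_green), line_id=str(r.line_id))
        for r in df.itertuples()
    ]


def write_phenotype_tsv(counts: Sequence[SegCounts], path) -> None:
    df = pd.DataFrame(
        {
            "line_id": [c.line_id for c in counts],
            "n_yellow": [c.n_yellow for c in counts],
            "n_green": [c.n_green for c in counts],
        }
    )
    df.to_csv(path, sep="\t", index=False)
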