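"""Shared test utilities: hand-rolled oracles and fixture builders."""

from __future__ import annotations

from math import comb

import numpy as np

from bsamap.fine_map import MarkerGenotype
from bsamap.synthetic_cross import CrossConfig, simulate_f2


def fisher_two_sided_exact(gi: int, go: int, yi: int, yo: int) -> float:
    """Independent oracle: two-sided Fisher P by exact integer enumeration.

    Table weights C(K,x)*C(M-K,n-x) are integers, so the "probability
    no larger than observed" rule is evaluated without floating-point
    ties.
    """
    M, K, n = gi + go + yi + yo, gi + yi, gi + go
    if M == 0:
        return 1.0
    lo, hi = max(0, n + K - M), min(K, n)
    weights = [comb(K, x) * comb(M - K, n - x) for x in range(lo, hi + 1)]
    w_obs = weights[gi - lo]
    return sum(w for w in weights if w <= w_obs) / comb(M, n)


def make_finemap_fixture(seed: int, n_lines: int = 200, locus: int = 987_654):
    """Error-free fine-mapping material around a planted locus.

    Returns (lines, triples, locus): ``lines`` maps line id to ordered
    marker calls on a 50-kb grid spanning the locus; ``triples`` are
    (line_id, calls, true causal genotype) ready for refine_interval.
    """
    cfg = CrossConfig(
        chrom_lengths=(("chr01", 2_000_000), ("chr02", 1_000_000)),
        causal_loci=(("chr01", locus), ("chr02", 500_000)),
        n_f2=n_lines,
        bulk_size=1,
        marker_spacing_bp=200_000,
        seed=seed,
    )
    population, _ = simulate_f2(cfg)
    markers = np.arange(200_000, 1_800_001, 50_000)
    names = np.array(["A", "H", "B"])
    lines: dict[str, list[MarkerGenotype]] = {}
    triples = []
    for i, ind in enumerate(population):
        codes = ind.genotype_code("chr01", markers)
        calls = [
            MarkerGenotype(f"m{j}", "chr01", int(p), str(names[c]))
            for j, (p, c) in enumerate(zip(markers, codes))
        ]
        genotype = str(names[int(ind.genotype_code("chr01", locus))])
        lines[f"L{i}"] = calls
        triples.append((f"L{i}", calls, genotype))
    return lines, triples, locus
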