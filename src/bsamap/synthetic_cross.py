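"""Synthetic biparental F2 cross with duplicate-dominant epistasis.

Simulates meiosis under the Haldane (no-interference) model along each
chromosome, builds an F2 population segregating for two unlinked
recessive causal loci (green phenotype only when double-homozygous for
the green-parent allele, giving the 15:1 yellow:green ratio), selects
phenotype bulks, and samples per-site sequencing depths for the two
parents and two bulks.  The dataset is written as a plain-text VCF plus
phenotype/marker tables and a truth file so every downstream stage of
the pipeline can be exercised without real sequencing data.

Ancestry coding: allele ``0`` = yellow parent (A), ``1`` = green parent
(B).  Genotypes are the count of green-parent alleles (0=AA, 1=AB,
2=BB).  All coordinates are 1-based inclusive.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "CrossConfig",
    "Haplotype",
    "Individual",
    "TruthSet",
    "SimulatedDataset",
    "YELLOW",
    "GREEN",
    "haldane_recomb_fraction",
    "make_gamete",
    "phenotype_of",
    "simulate_f2",
    "select_bulks",
    "make_marker_ladder",
    "bulk_allele_freqs",
    "simulate_depths",
    "simulate_f3_counts",
    "simulate_dataset",
    "write_dataset",
    "default_config",
]

YELLOW = "yellow"
GREEN = "green"

_GT_CODES = {"AA": 0, "AB": 1, "BB": 2}
_GT_NAMES = {v: k for k, v in _GT_CODES.items()}


@dataclass(frozen=True)
class CrossConfig:
    """Parameters of the simulated cross and sequencing experiment."""

    chrom_lengths: tuple[tuple[str, int], ...]
    causal_loci: tuple[tuple[str, int], ...]
    cm_per_mb: float = 2.5
    n_f2: int = 495
    bulk_size: int = 30
    marker_spacing_bp: int = 10_000
    depth_bulk: float = 55.0
    depth_parent: float = 10.0
    seq_error: float = 0.001
    f3_seeds_per_line: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        lengths = dict(self.chrom_lengths)
        if len(self.causal_loci) not in (0, 2):
            raise ValueError("exactly two causal loci required (or none for a null cross)")
        for chrom, pos in self.causal_loci:
            if chrom not in lengths:
                raise ValueError(f"causal locus chromosome {chrom!r} not in genome")
            if not 1 <= pos <= lengths[chrom]:
                raise ValueError(f"causal locus {chrom}:{pos} outside chromosome")
        for name, value in [
            ("cm_per_mb", self.cm_per_mb),
            ("depth_bulk", self.depth_bulk),
            ("depth_parent", self.depth_parent),
            ("marker_spacing_bp", self.marker_spacing_bp),
        ]:
            if value <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.seq_error < 0.5:
            raise ValueError("seq_error must be in [0, 0.5)")
        if self.n_f2 < 1 or self.bulk_size < 1:
            raise ValueError("n_f2 and bulk_size must be >= 1")

    @property
    def is_null(self) -> bool:
        """True when no causal loci are planted (false-positive studies)."""
        return len(self.causal_loci) == 0

    @classmethod
    def from_yaml(cls, path) -> "CrossConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["chrom_lengths"] = tuple((str(c), int(l)) for c, l in raw["chrom_lengths"])
        raw["causal_loci"] = tuple((str(c), int(p)) for c, p in raw.get("causal_loci", []))
        return cls(**raw)


def default_config(seed: int = 0) -> CrossConfig:
    """Two 50-Mb chromosomes with one causal locus planted on each."""
    return CrossConfig(
        chrom_lengths=(("chr01", 50_000_000), ("chr02", 50_000_000)),
        causal_loci=(("chr01", 25_000_000), ("chr02", 10_000_000)),
        seed=seed,
    )


@dataclass(frozen=True)
class Haplotype:
    """One chromosome copy as an ancestry mosaic.

    ``breaks`` are crossover positions in bp, sorted ascending; ancestry
    starts at ``start`` (0 or 1) and flips after each break.  The blocks
    implied by the breaks tile [1, length] exactly.
    """

    start: int
    breaks: np.ndarray
    length: int

    def ancestry_at(self, pos) -> np.ndarray:
        """Ancestry (0/1) at one or more bp positions (vectorized)."""
        idx = np.searchsorted(self.breaks, np.asarray(pos), side="left")
        return (self.start + idx) % 2

    def blocks(self) -> list[tuple[int, int, int]]:
        """(start_bp, end_bp, ancestry) blocks tiling the chromosome."""
        edges = [1] + [int(math.floor(b)) + 1 for b in self.breaks] + [self.length + 1]
        out = []
        anc = self.start
        for lo, hi in zip(edges[:-1], edges[1:]):
            if hi > lo:
                out.append((lo, hi - 1, anc))
            anc ^= 1
        return out


@dataclass
class Individual:
    """Diploid individual: two haplotypes per chromosome."""

    haplotypes: dict[str, tuple[Haplotype, Haplotype]]
    phenotype: str | None = None

    def genotype_code(self, chrom: str, pos) -> np.ndarray:
        """Count of green-parent alleles (0/1/2) at bp position(s)."""
        h1, h2 = self.haplotypes[chrom]
        return h1.ancestry_at(pos) + h2.ancestry_at(pos)

    def genotype(self, chrom: str, pos: int) -> str:
        return _GT_NAMES[int(self.genotype_code(chrom, pos))]


@dataclass
class TruthSet:
    """Ground truth of one simulated cross."""

    causal_loci: tuple[tuple[str, int], ...]
    genotypes: np.ndarray  # (n_f2, n_causal) codes 0/1/2
    phenotypes: list[str]
    yellow_bulk: list[int] = field(default_factory=list)
    green_bulk: list[int] = field(default_factory=list)
    bulk_freqs: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    def validate_bulks(self) -> None:
        for i in self.green_bulk:
            if not all(g == 2 for g in self.genotypes[i]):
                raise AssertionError(
                    f"green-bulk member {i} is not double-homozygous recessive"
                )


def haldane_recomb_fraction(d_cm: float) -> float:
    """Recombination fraction for a map distance in centiMorgan."""
    return 0.5 * (1.0 - math.exp(-2.0 * d_cm / 100.0))


def _founder(code: int, chrom_lengths) -> Individual:
    haps = {
        chrom: (
            Haplotype(code, np.empty(0), length),
            Haplotype(code, np.empty(0), length),
        )
        for chrom, length in chrom_lengths
    }
    return Individual(haps)


def _f1(chrom_lengths) -> Individual:
    haps = {
        chrom: (
            Haplotype(0, np.empty(0), length),
            Haplotype(1, np.empty(0), length),
        )
        for chrom, length in chrom_lengths
    }
    return Individual(haps)


def make_gamete(
    parent: Individual, rng: np.random.Generator, cm_per_mb: float = 2.5
) -> dict[str, Haplotype]:
    """One recombinant gamete (one haplotype per chromosome).

    Crossovers follow a Poisson process along the genetic map (Haldane
    model, no interference): the count per chromosome is Poisson with
    mean equal to the map length in Morgans and positions are uniform.
    Chromosomes assort independently.
    """
    gamete: dict[str, Haplotype] = {}
    for chrom, (h1, h2) in parent.haplotypes.items():
        length = h1.length
        morgans = cm_per_mb * length / 1e6 / 100.0
        n_co = rng.poisson(morgans)
        xovers = np.sort(rng.uniform(0.0, length, size=n_co))
        first = int(rng.integers(2))
        if h1.breaks.size == 0 and h2.breaks.size == 0:
            # uniform templates: the gamete mosaic is just the switch track
            if h1.start == h2.start:
                gamete[chrom] = Haplotype(h1.start, np.empty(0), length)
            else:
                start = h1.start if first == 0 else h2.start
                gamete[chrom] = Haplotype(start, xovers, length)
            continue
        # merge the crossover switch-track with both template mosaics
        cand = np.unique(np.concatenate([xovers, h1.breaks, h2.breaks]))
        probe = np.concatenate([[0.5 * cand[0] if cand.size else 1.0],
                                0.5 * (cand[:-1] + cand[1:]) if cand.size > 1 else np.empty(0),
                                [cand[-1] + 1.0] if cand.size else np.empty(0)])
        which = (first + np.searchsorted(xovers, probe, side="left")) % 2
        h1a = h1.ancestry_at(probe)
        h2a = h2.ancestry_at(probe)
        anc = np.where(which == 0, h1a, h2a)
        flips = np.flatnonzero(anc[1:] != anc[:-1])
        gamete[chrom] = Haplotype(int(anc[0]), cand[flips], length)
    return gamete


def phenotype_of(genotype_locus1: str | int, genotype_locus2: str | int) -> str:
    """Green only when both causal loci are homozygous green-parent."""

    def code(g):
        if isinstance(g, str):
            if g not in _GT_CODES:
                raise ValueError(f"invalid genotype code {g!r}")
            return _GT_CODES[g]
        if g not in (0, 1, 2):
            raise ValueError(f"invalid genotype code {g!r}")
        return g

    return GREEN if code(genotype_locus1) == 2 and code(genotype_locus2) == 2 else YELLOW


def simulate_f2(
    config: CrossConfig, rng: np.random.Generator | None = None
) -> tuple[list[Individual], TruthSet]:
    """Simulate the F2 population by selfing the F1.

    Each F2 individual is formed from two independent F1 gametes; its
    phenotype follows the two-locus recessive epistasis model.  Null
    crosses (no causal loci) produce all-yellow populations.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    f1 = _f1(config.chrom_lengths)
    population: list[Individual] = []
    n_causal = len(config.causal_loci)
    genotypes = np.zeros((config.n_f2, n_causal), dtype=np.int8)
    phenotypes: list[str] = []
    for i in range(config.n_f2):
        g1 = make_gamete(f1, rng, config.cm_per_mb)
        g2 = make_gamete(f1, rng, config.cm_per_mb)
        ind = Individual({c: (g1[c], g2[c]) for c in g1})
        for j, (chrom, pos) in enumerate(config.causal_loci):
            genotypes[i, j] = ind.genotype_code(chrom, pos)
        if n_causal == 2:
            ind.phenotype = phenotype_of(int(genotypes[i, 0]), int(genotypes[i, 1]))
        else:
            ind.phenotype = YELLOW
        phenotypes.append(ind.phenotype)
        population.append(ind)
    truth = TruthSet(config.causal_loci, genotypes, phenotypes)
    return population, truth


def select_bulks(
    population: Sequence[Individual],
    truth: TruthSet,
    bulk_size: int,
    rng: np.random.Generator,
    ignore_phenotype: bool = False,
) -> tuple[list[int], list[int]]:
    """Sample ``bulk_size`` members per phenotype without replacement.

    With ``ignore_phenotype`` both bulks are random draws from the whole
    population (null-model bulks).  Raises if a phenotype class is
    smaller than the requested bulk.
    """
    if ignore_phenotype:
        picks = rng.choice(len(population), size=2 * bulk_size, replace=False)
        yellow = sorted(int(i) for i in picks[:bulk_size])
        green = sorted(int(i) for i in picks[bulk_size:])
    else:
        yellows = [i for i, p in enumerate(truth.phenotypes) if p == YELLOW]
        greens = [i for i, p in enumerate(truth.phenotypes) if p == GREEN]
        for label, pool in ((YELLOW, yellows), (GREEN, greens)):
            if len(pool) < bulk_size:
                raise ValueError(
                    f"only {len(pool)} {label} individuals available, "
                    f"need {bulk_size} for the bulk"
                )
        yellow = sorted(int(i) for i in rng.choice(yellows, bulk_size, replace=False))
        green = sorted(int(i) for i in rng.choice(greens, bulk_size, replace=False))
    truth.yellow_bulk = yellow
    truth.green_bulk = green
    if not ignore_phenotype:
        truth.validate_bulks()
    return yellow, green


def make_marker_ladder(
    config: CrossConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Random informative-SNP positions at the configured mean spacing.

    Causal loci are always included as markers so truth frequencies are
    observable at them.
    """
    ladder: dict[str, np.ndarray] = {}
    causal = {}
    for chrom, pos in config.causal_loci:
        causal.setdefault(chrom, []).append(pos)
    for chrom, length in config.chrom_lengths:
        n = min(max(1, int(round(length / config.marker_spacing_bp))), length)
        # rejection sampling of distinct positions; collisions are rare
        # at the intended sparse densities
        pos = np.unique(rng.integers(1, length + 1, size=n))
        while len(pos) < n:
            extra = rng.integers(1, length + 1, size=n - len(pos))
            pos = np.unique(np.concatenate([pos, extra]))
        pos = np.union1d(pos, np.asarray(causal.get(chrom, []), dtype=np.int64))
        ladder[chrom] = pos.astype(np.int64)
    return ladder


def bulk_allele_freqs(
    population: Sequence[Individual],
    members: Sequence[int],
    ladder: Mapping[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """True green-parent allele frequency per marker in one bulk."""
    freqs: dict[str, np.ndarray] = {}
    for chrom, positions in ladder.items():
        total = np.zeros(len(positions), dtype=np.int64)
        for i in members:
            total += population[i].genotype_code(chrom, positions)
        freqs[chrom] = total / (2.0 * len(members))
    return freqs


def simulate_depths(
    freqs: Mapping[str, np.ndarray],
    mean_depth: float,
    seq_error: float,
    rng: np.random.Generator,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-site (other_reads, green_reads) for one sample.

    Total depth is Poisson(mean_depth); the number of reads carrying the
    green-parent allele is Binomial(depth, f(1-e) + (1-f)e) where ``f``
    is the sample's true green-allele frequency.
    """
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, f in freqs.items():
        f = np.asarray(f, dtype=float)
        if ((f < 0) | (f > 1)).any():
            raise ValueError("allele frequencies must lie in [0, 1]")
        depth = rng.poisson(mean_depth, size=f.shape)
        p = f * (1 - seq_error) + (1 - f) * seq_error
        green = rng.binomial(depth, p)
        out[chrom] = (depth - green, green)
    return out


def simulate_f3_counts(
    truth: TruthSet, config: CrossConfig, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Selfed-progeny (yellow, green) seed counts per F2 line.

    Linkage is ignored within a family: the green-seed probability is
    the product of the per-locus homozygous-recessive probabilities
    under selfing (0, 1/4 or 1 for genotype codes 0, 1, 2).
    """
    q = np.array([0.0, 0.25, 1.0])
    n = config.f3_seeds_per_line
    counts = []
    for gts in truth.genotypes:
        p_green = float(np.prod(q[list(gts)])) if len(gts) else 0.0
        green = int(rng.binomial(n, p_green))
        counts.append((n - green, green))
    return counts


@dataclass
class SimulatedDataset:
    """Everything produced by one simulation, ready for serialization."""

    config: CrossConfig
    population: list[Individual]
    truth: TruthSet
    ladder: dict[str, np.ndarray]
    ref_alleles: dict[str, np.ndarray]
    alt_alleles: dict[str, np.ndarray]
    green_is_alt: dict[str, np.ndarray]
    quals: dict[str, np.ndarray]
    depths: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]  # sample -> chrom
    f3_counts: list[tuple[int, int]]


_BASES = np.array(list("ACGT"))


def simulate_dataset(config: CrossConfig) -> SimulatedDataset:
    """Run the full simulation for one seeded config."""
    rng = np.random.default_rng(config.seed)
    # re-draw the population when a phenotype class is smaller than the
    # bulk (at n_f2=495 and p=1/16 the green class falls short of 30 in
    # a sizeable fraction of draws); deterministic given the seed
    for attempt in range(1000):
        population, truth = simulate_f2(config, rng)
        if config.is_null:
            break
        n_green = truth.phenotypes.count(GREEN)
        n_yellow = truth.phenotypes.count(YELLOW)
        if n_green >= config.bulk_size and n_yellow >= config.bulk_size:
            break
    else:
        raise RuntimeError("could not draw a population with enough of each phenotype")
    yellow, green = select_bulks(
        population, truth, config.bulk_size, rng, ignore_phenotype=config.is_null
    )
    ladder = make_marker_ladder(config, rng)
    freq_yellow = bulk_allele_freqs(population, yellow, ladder)
    freq_green = bulk_allele_freqs(population, green, ladder)
    truth.bulk_freqs = {"bulk_yellow": freq_yellow, "bulk_green": freq_green}
    ones = {c: np.ones(len(p)) for c, p in ladder.items()}
    zeros = {c: np.zeros(len(p)) for c, p in ladder.items()}
    depths = {
        "parent_yellow": simulate_depths(zeros, config.depth_parent, config.seq_error, rng),
        "parent_green": simulate_depths(ones, config.depth_parent, config.seq_error, rng),
        "bulk_yellow": simulate_depths(freq_yellow, config.depth_bulk, config.seq_error, rng),
        "bulk_green": simulate_depths(freq_green, config.depth_bulk, config.seq_error, rng),
    }
    ref_alleles, alt_alleles, green_is_alt, quals = {}, {}, {}, {}
    for chrom, pos in ladder.items():
        n = len(pos)
        ref_idx = rng.integers(0, 4, size=n)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
        ref_alleles[chrom] = _BASES[ref_idx]
        alt_alleles[chrom] = _BASES[alt_idx]
        green_is_alt[chrom] = rng.random(n) < 0.5
        # integral QUAL so the float32 VCF round trip is exact
        quals[chrom] = np.round(rng.uniform(200.0, 1000.0, size=n))
    f3 = simulate_f3_counts(truth, config, rng)
    return SimulatedDataset(
        config, population, truth, ladder, ref_alleles, alt_alleles,
        green_is_alt, quals, depths, f3,
    )


def _vcf_sample_field(gt: str, ref_d: int, alt_d: int) -> str:
    return f"{gt}:{ref_d},{alt_d}:{ref_d + alt_d}"


SAMPLE_ORDER = ("parent_yellow", "parent_green", "bulk_yellow", "bulk_green")


def write_vcf(dataset: SimulatedDataset, path) -> None:
    """Plain-text VCF 4.2 with GT for parents and AD/DP for all samples."""
    cfg = dataset.config
    lines = ["##fileformat=VCFv4.2", "##source=bsamap-simulate"]
    for chrom, length in cfg.chrom_lengths:
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(SAMPLE_ORDER),
    ]
    for chrom, _ in cfg.chrom_lengths:
        positions = dataset.ladder[chrom]
        refs = dataset.ref_alleles[chrom]
        alts = dataset.alt_alleles[chrom]
        gia = dataset.green_is_alt[chrom]
        quals = dataset.quals[chrom]
        for i, pos in enumerate(positions):
            green_alt = bool(gia[i])
            gt_green = "1/1" if green_alt else "0/0"
            gt_yellow = "0/0" if green_alt else "1/1"
            fields = []
            for sample in SAMPLE_ORDER:
                other, green = dataset.depths[sample][chrom]
                o, g = int(other[i]), int(green[i])
                ref_d, alt_d = (o, g) if green_alt else (g, o)
                if sample == "parent_yellow":
                    gt = gt_yellow
                elif sample == "parent_green":
                    gt = gt_green
                else:
                    gt = "./."
                fields.append(_vcf_sample_field(gt, ref_d, alt_d))
            lines.append(
                f"{chrom}\t{int(pos)}\t.\t{refs[i]}\t{alts[i]}\t{quals[i]:g}"
                f"\tPASS\t.\tGT:AD:DP\t" + "\t".join(fields)
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_marker_genotypes(
    dataset: SimulatedDataset,
    path,
    halfwidth_bp: int = 500_000,
    marker_step: int = 5,
) -> None:
    """Marker calls (A/H/B) for every F2 line around each causal locus.

    Markers are taken from the simulated ladder within ``halfwidth_bp``
    of a causal locus, thinned to every ``marker_step``-th site.
    """
    rows = ["line_id\tmarker_id\tchrom\tpos\tcall"]
    call_names = np.array(["A", "H", "B"])
    for chrom, locus in dataset.truth.causal_loci:
        positions = dataset.ladder[chrom]
        near = positions[np.abs(positions - locus) <= halfwidth_bp]
        near = np.union1d(near[::marker_step], [locus])
        for li, ind in enumerate(dataset.population):
            codes = ind.genotype_code(chrom, near)
            for pos, code in zip(near, codes):
                rows.append(
                    f"L{li:04d}\t{chrom}_{int(pos)}\t{chrom}\t{int(pos)}\t{call_names[code]}"
                )
    Path(path).write_text("\n".join(rows) + "\n")


def write_dataset(dataset: SimulatedDataset, outdir) -> dict[str, Path]:
    """Serialize one simulation: VCF, phenotype TSV, marker TSV, truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "markers.vcf",
        "phenotypes": outdir / "phenotypes.tsv",
        "markers": outdir / "marker_genotypes.tsv",
        "truth": outdir / "truth.json",
    }
    write_vcf(dataset, paths["vcf"])

    pheno_rows = ["line_id\tn_yellow\tn_green"]
    for i, (ny, ng) in enumerate(dataset.f3_counts):
        pheno_rows.append(f"L{i:04d}\t{ny}\t{ng}")
    paths["phenotypes"].write_text("\n".join(pheno_rows) + "\n")

    write_marker_genotypes(dataset, paths["markers"])

    truth = dataset.truth
    truth_obj = {
        "causal_loci": [[c, int(p)] for c, p in truth.causal_loci],
        "genotypes": truth.genotypes.tolist(),
        "phenotypes": truth.phenotypes,
        "yellow_bulk": truth.yellow_bulk,
        "green_bulk": truth.green_bulk,
        "bulk_freqs": {
            bulk: {c: np.round(f, 6).tolist() for c, f in freqs.items()}
            for bulk, freqs in truth.bulk_freqs.items()
        },
        "marker_positions": {c: p.tolist() for c, p in dataset.ladder.items()},
    }
    paths["truth"].write_text(json.dumps(truth_obj, indent=1))
    return paths
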