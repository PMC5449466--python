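import json
import shutil
import subprocess
from dataclasses import replace
from itertools import product

import numpy as np
import pytest

from bsamap.segregation import SegCounts, chi2_gof
from bsamap.synthetic_cross import (
    GREEN,
    YELLOW,
    CrossConfig,
    Haplotype,
    Individual,
    TruthSet,
    bulk_allele_freqs,
    default_config,
    haldane_recomb_fraction,
    make_gamete,
    make_marker_ladder,
    phenotype_of,
    select_bulks,
    simulate_dataset,
    simulate_depths,
    simulate_f2,
    simulate_f3_counts,
    write_dataset,
)
from bsamap.variant_filter import read_variants


def _f1_like(length=1_000_000, chrom="c1"):
    return Individual(
        {chrom: (Haplotype(0, np.empty(0), length), Haplotype(1, np.empty(0), length))}
    )


class TestHaldane:
    def test_zero_distance(self):
        assert haldane_recomb_fraction(0.0) == 0.0

    def test_asymptote(self):
        assert haldane_recomb_fraction(1e9) == pytest.approx(0.5)

    def test_one_mb_at_default_density(self):
        # 1 Mb at 2.5 cM/Mb: r = (1 - exp(-0.05)) / 2
        assert haldane_recomb_fraction(2.5) == pytest.approx(0.0243853, abs=1e-6)

    def test_monotone_increasing(self):
        d = np.linspace(0, 200, 50)
        r = [haldane_recomb_fraction(x) for x in d]
        assert all(b > a for a, b in zip(r, r[1:]))


class TestMakeGamete:
    def test_recomb_fraction_matches_haldane(self):
        rng = np.random.default_rng(42)
        parent = _f1_like()
        n = 10_000
        switches = 0
        for _ in range(n):
            hap = make_gamete(parent, rng)["c1"]
            a = hap.ancestry_at(np.array([1, 1_000_000]))
            switches += a[0] != a[1]
        expected = haldane_recomb_fraction(2.5)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(switches / n - expected) < 4 * se

    def test_adjacent_positions_co_inherited(self):
        rng = np.random.default_rng(7)
        parent = _f1_like()
        for _ in range(2_000):
            hap = make_gamete(parent, rng)["c1"]
            a = hap.ancestry_at(np.array([500_000, 500_001]))
            assert a[0] == a[1]

    def test_general_mosaic_parent(self):
        # recombinant parent: gamete ancestry must come from one of the
        # two templates at every position
        rng = np.random.default_rng(3)
        h1 = Haplotype(0, np.array([300_000.0]), 1_000_000)
        h2 = Haplotype(1, np.array([700_000.0]), 1_000_000)
        parent = Individual({"c1": (h1, h2)})
        pos = np.arange(1, 1_000_001, 9_973)
        for _ in range(50):
            hap = make_gamete(parent, rng, cm_per_mb=50.0)["c1"]
            anc = hap.ancestry_at(pos)
            a1, a2 = h1.ancestry_at(pos), h2.ancestry_at(pos)
            assert np.all((anc == a1) | (anc == a2))


class TestPhenotype:
    def test_double_recessive_is_green(self):
        assert phenotype_of("BB", "BB") == GREEN

    def test_dominant_allele_is_yellow(self):
        assert phenotype_of("AA", "BB") == YELLOW

    def test_integer_codes(self):
        assert phenotype_of(2, 2) == GREEN
        assert phenotype_of(1, 2) == YELLOW

    def test_invalid_code_raises(self):
        with pytest.raises(ValueError):
            phenotype_of("BC", "BB")
        with pytest.raises(ValueError):
            phenotype_of(3, 0)

    def test_green_fraction_by_enumeration(self):
        # oracle: enumerate the 16 equiprobable two-locus gamete combos
        green = sum(
            phenotype_of(m1 + p1, m2 + p2) == GREEN
            for m1, p1, m2, p2 in product((0, 1), repeat=4)
        )
        assert green == 1  # 15:1 yellow:green


class TestSimulateF2:
    CFG = CrossConfig(
        chrom_lengths=(("c1", 1_000_000), ("c2", 1_000_000)),
        causal_loci=(("c1", 500_000), ("c2", 500_000)),
        n_f2=200,
        bulk_size=5,
        marker_spacing_bp=100_000,
        seed=5,
    )

    def test_deterministic_given_seed(self):
        _, t1 = simulate_f2(self.CFG)
        _, t2 = simulate_f2(self.CFG)
        assert np.array_equal(t1.genotypes, t2.genotypes)
        assert t1.phenotypes == t2.phenotypes

    def test_ratio_fits_15_to_1_at_large_n(self):
        cfg = replace(self.CFG, n_f2=10_000, seed=1)
        _, truth = simulate_f2(cfg)
        n_green = truth.phenotypes.count(GREEN)
        counts = SegCounts(cfg.n_f2 - n_green, n_green)
        assert chi2_gof(counts, (15, 1)).p_uncorrected >= 0.01

    def test_diploid_closure(self):
        population, _ = simulate_f2(self.CFG)
        pos = np.array([1, 123_456, 999_999])
        for ind in population[:20]:
            codes = ind.genotype_code("c1", pos)
            assert np.isin(codes, [0, 1, 2]).all()

    def test_blocks_tile_chromosome(self):
        population, _ = simulate_f2(replace(self.CFG, cm_per_mb=50.0, seed=9))
        for ind in population[:30]:
            for chrom, (h1, h2) in ind.haplotypes.items():
                for hap in (h1, h2):
                    blocks = hap.blocks()
                    assert blocks[0][0] == 1
                    assert blocks[-1][1] == hap.length
                    for (_, end, _), (start, _, _) in zip(blocks, blocks[1:]):
                        assert start == end + 1

    def test_phenotype_ratio_over_replicates(self):
        # mean green fraction over R replicates within 3 MC standard
        # errors of 1/16
        reps = 200
        n_f2 = 495
        fractions = []
        for seed in range(reps):
            cfg = replace(self.CFG, n_f2=n_f2, seed=seed)
            _, truth = simulate_f2(cfg)
            fractions.append(truth.phenotypes.count(GREEN) / n_f2)
        p = 1 / 16
        se = np.sqrt(p * (1 - p) / n_f2 / reps)
        assert abs(np.mean(fractions) - p) < 3 * se


class TestSelectBulks:
    def test_green_bulk_fixed_at_causal_loci(self, small_dataset):
        truth = small_dataset.truth
        for j, (chrom, pos) in enumerate(truth.causal_loci):
            idx = int(np.searchsorted(small_dataset.ladder[chrom], pos))
            assert truth.bulk_freqs["bulk_green"][chrom][idx] == 1.0

    def test_yellow_bulk_causal_frequency_near_7_15(self):
        cfg = replace(TestSimulateF2.CFG, n_f2=400, bulk_size=25)
        freqs = []
        for seed in range(30):
            ds = simulate_dataset(replace(cfg, seed=seed))
            for chrom, pos in cfg.causal_loci:
                idx = int(np.searchsorted(ds.ladder[chrom], pos))
                freqs.append(ds.truth.bulk_freqs["bulk_yellow"][chrom][idx])
        assert abs(np.mean(freqs) - 7 / 15) < 0.03

    def test_unlinked_marker_frequency_near_half(self):
        # third chromosome carries no causal locus
        cfg = CrossConfig(
            chrom_lengths=(("c1", 1_000_000), ("c2", 1_000_000), ("c3", 1_000_000)),
            causal_loci=(("c1", 500_000), ("c2", 500_000)),
            n_f2=300,
            bulk_size=15,
            marker_spacing_bp=50_000,
        )
        means = []
        for seed in range(12):
            ds = simulate_dataset(replace(cfg, seed=seed))
            for bulk in ("bulk_yellow", "bulk_green"):
                means.append(np.mean(ds.truth.bulk_freqs[bulk]["c3"]))
        assert abs(np.mean(means) - 0.5) < 0.05

    def test_shortfall_fails_loudly(self):
        population, truth = simulate_f2(
            replace(TestSimulateF2.CFG, n_f2=20, seed=2)
        )
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="green"):
            select_bulks(population, truth, 10, rng)

    def test_bulk_members_match_phenotype(self):
        population, truth = simulate_f2(replace(TestSimulateF2.CFG, n_f2=600))
        rng = np.random.default_rng(1)
        yellow, green = select_bulks(population, truth, 10, rng)
        assert all(truth.phenotypes[i] == YELLOW for i in yellow)
        assert all(truth.phenotypes[i] == GREEN for i in green)
        assert len(set(yellow)) == len(set(green)) == 10


class TestSimulateDepths:
    def test_degenerate_all_index_allele(self):
        rng = np.random.default_rng(0)
        other, green = simulate_depths({"c": np.ones(500)}, 30, 0.0, rng)["c"]
        assert (other == 0).all()
        assert (green + other > 0).any()

    def test_degenerate_no_index_allele(self):
        rng = np.random.default_rng(0)
        other, green = simulate_depths({"c": np.zeros(500)}, 30, 0.0, rng)["c"]
        assert (green == 0).all()

    def test_mean_depth_matches_poisson(self):
        rng = np.random.default_rng(1)
        other, green = simulate_depths({"c": np.full(20_000, 0.5)}, 55, 0.001, rng)["c"]
        total = other + green
        assert abs(total.mean() - 55) / 55 < 0.02

    def test_invalid_frequency_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            simulate_depths({"c": np.array([1.5])}, 10, 0.0, rng)


class TestSimulateF3:
    def _truth(self, genotype, n=2000):
        return TruthSet(
            (("c1", 1), ("c2", 1)),
            np.tile(np.array(genotype, dtype=np.int8), (n, 1)),
            [YELLOW] * n,
        )

    def _green_fraction(self, genotype, seed=0):
        cfg = TestSimulateF2.CFG
        truth = self._truth(genotype)
        counts = simulate_f3_counts(truth, cfg, np.random.default_rng(seed))
        total = sum(y + g for y, g in counts)
        return sum(g for _, g in counts) / total

    def test_fixed_dominant_locus_blocks_green(self):
        assert self._green_fraction((0, 2)) == 0.0

    def test_single_het_locus_segregates_quarter(self):
        assert self._green_fraction((1, 2)) == pytest.approx(0.25, abs=0.01)

    def test_double_het_segregates_sixteenth(self):
        assert self._green_fraction((1, 1)) == pytest.approx(1 / 16, abs=0.005)

    def test_counts_sum_to_seeds_per_line(self):
        cfg = TestSimulateF2.CFG
        counts = simulate_f3_counts(
            self._truth((1, 1), n=50), cfg, np.random.default_rng(0)
        )
        assert all(y + g == cfg.f3_seeds_per_line for y, g in counts)


class TestWriteDataset:
    def test_depth_round_trip(self, small_dataset, sim_paths):
        sites = list(read_variants(sim_paths["vcf"]))
        by_pos = {(s.chrom, s.pos): s for s in sites}
        for chrom, _ in small_dataset.config.chrom_lengths:
            other, green = small_dataset.depths["bulk_green"][chrom]
            gia = small_dataset.green_is_alt[chrom]
            for i, pos in enumerate(small_dataset.ladder[chrom]):
                site = by_pos[(chrom, int(pos))]
                got_green = site.bulk_green_alt if gia[i] else site.bulk_green_ref
                got_other = site.bulk_green_ref if gia[i] else site.bulk_green_alt
                assert (got_green, got_other) == (int(green[i]), int(other[i]))

    def test_vcf_passes_external_validator(self, sim_paths):
        if shutil.which("bcftools") is None:
            pytest.skip("bcftools not available")
        res = subprocess.run(
            ["bcftools", "view", str(sim_paths["vcf"])],
            capture_output=True,
            text=True,
        )
        assert res.returncode == 0, res.stderr

    def test_truth_json_has_two_causal_loci(self, sim_paths):
        truth = json.loads(sim_paths["truth"].read_text())
        assert len(truth["causal_loci"]) == 2

    def test_byte_identical_given_seed(self, small_cross, tmp_path):
        a = write_dataset(simulate_dataset(small_cross), tmp_path / "a")
        b = write_dataset(simulate_dataset(small_cross), tmp_path / "b")
        for key in a:
            assert a[key].read_bytes() == b[key].read_bytes(), key

    def test_phenotype_table_shape(self, small_cross, sim_paths):
        lines = sim_paths["phenotypes"].read_text().strip().splitlines()
        assert lines[0] == "line_id\tn_yellow\tn_green"
        assert len(lines) == small_cross.n_f2 + 1


class TestConfigValidation:
    def test_one_causal_locus_rejected(self):
        with pytest.raises(ValueError, match="causal"):
            CrossConfig(
                chrom_lengths=(("c1", 1000),), causal_loci=(("c1", 500),)
            )

    def test_locus_outside_chromosome(self):
        with pytest.raises(ValueError, match="outside"):
            CrossConfig(
                chrom_lengths=(("c1", 1000), ("c2", 1000)),
                causal_loci=(("c1", 5000), ("c2", 500)),
            )

    def test_null_cross_allowed(self):
        cfg = CrossConfig(chrom_lengths=(("c1", 1000),), causal_loci=())
        assert cfg.is_null

    def test_bad_rates_rejected(self):
        with pytest.raises(ValueError):
            CrossConfig(
                chrom_lengths=(("c1", 1000), ("c2", 1000)),
                causal_loci=(("c1", 500), ("c2", 500)),
                depth_bulk=0,
            )

    def test_default_config_valid(self):
        cfg = default_config(seed=3)
        assert cfg.seed == 3
        assert len(cfg.causal_loci) == 2

    def test_marker_ladder_contains_causal_loci(self):
        cfg = TestSimulateF2.CFG
        ladder = make_marker_ladder(cfg, np.random.default_rng(0))
        for chrom, pos in cfg.causal_loci:
            assert pos in ladder[chrom]
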