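# bsamap

Bulked-segregant analysis sequencing (BSA-seq) mapping toolkit for a
biparental cross segregating for two unlinked recessive loci
(duplicate-dominant epistasis, 15:1 phenotype ratio).

The package covers the full desk-scale workflow:

- **`bsamap.synthetic_cross`** — seeded F2 cross simulator: Haldane
  (no-interference) meiosis along each chromosome, two-locus recessive
  phenotype model, phenotype bulks, Poisson/binomial sequencing depths,
  and serialization to a four-sample VCF plus phenotype, marker-genotype
  and truth files.
- **`bsamap.variant_filter`** — reads the four-sample VCF (two parents,
  two bulks), keeps biallelic SNPs with opposite-homozygous parents,
  QUAL ≥ 100 and depth ≥ 10 in both bulks, and polarizes each site so
  the index allele is the green-parent allele.
- **`bsamap.bsa_index`** — per-site SNP-index in each bulk,
  Δ(SNP-index) (green minus yellow), and a two-sided Fisher exact test
  of the 2×2 bulk-by-allele read-count table (vectorized batch variant
  included).
- **`bsamap.window_scan`** — sliding-window averaging (2-Mb windows,
  10-kb step by default) and candidate-region calling (mean green-bulk
  index > 0.9 and mean P < 0.05), with TSV/BED output and scan plots.
- **`bsamap.segregation`** — goodness-of-fit chi-square for arbitrary
  segregation ratios (Yates-corrected and uncorrected), F2:3 family
  classification (all-dominant / 3:1 / 15:1 / all-recessive), and the
  7:4:4:1 two-gene model test.
- **`bsamap.fine_map`** — controlling-locus assignment for 3:1 lines,
  recombinant breakpoint detection, and interval refinement by
  intersecting recombinant constraints.
- **`bsamap.pipeline`** — one-command orchestration with a seeded
  deterministic end-to-end run and a replicate recovery/power study.

## Test

```sh
python -m pytest -q tests/
```

The suite (≈200 tests, ~1 min) includes property tests
(hypothesis), exact-enumeration oracles for the Fisher test, and
simulation-based acceptance tests for region recovery and fine mapping.

## Command line

```sh
# end-to-end: simulate the built-in two-chromosome cross, then
# filter -> SNP-index -> sliding-window scan -> regions + plots
bsamap run --outdir out --seed 1

# individual stages
bsamap simulate --outdir sim --seed 1
bsamap filter --vcf sim/markers.vcf --out sites.tsv
bsamap index --sites sites.tsv --out index.tsv
bsamap scan --index index.tsv --genome genome.txt --out scan/

# segregation statistics and F2:3 classification
bsamap segtest --pheno sim/phenotypes.tsv --ratio 15:1
bsamap classify --pheno sim/phenotypes.tsv

# recombinant-based fine mapping around a candidate region
bsamap finemap --geno sim/marker_genotypes.tsv \
               --pheno sim/phenotypes.tsv --region chr01:24500000-25500000

# replicate power study
bsamap recovery-study --replicates 20 --out study.tsv
```

A custom cross is described by a YAML file
(`chrom_lengths: [[chr01, 50000000], ...]`, `causal_loci: [[chr01,
25000000], [chr02, 10000000]]`, plus optional `n_f2`, `bulk_size`,
`depth_bulk`, `seq_error`, …) passed via `--config`.

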