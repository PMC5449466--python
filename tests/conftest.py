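import pytest

from bsamap.pipeline import RunConfig, run_bsaseq
from bsamap.synthetic_cross import CrossConfig, default_config, simulate_dataset, write_dataset

# Small, fast cross used by most unit tests.
SMALL_CROSS = CrossConfig(
    chrom_lengths=(("chr01", 2_000_000), ("chr02", 2_000_000)),
    causal_loci=(("chr01", 1_000_000), ("chr02", 600_000)),
    n_f2=300,
    bulk_size=10,
    marker_spacing_bp=20_000,
    seed=11,
)


@pytest.fixture(scope="session")
def small_cross():
    return SMALL_CROSS


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(SMALL_CROSS)


@pytest.fixture(scope="session")
def sim_paths(tmp_path_factory, small_dataset):
    """Serialized small dataset (VCF, phenotype TSV, marker TSV, truth)."""
    outdir = tmp_path_factory.mktemp("sim")
    return write_dataset(small_dataset, outdir)


@pytest.fixture(scope="session")
def recovery_runs(tmp_path_factory):
    """20 seeded end-to-end runs at the default simulation scale.

    Shared by the region-recovery invariant tests and the acceptance
    suite (the runs are by far the most expensive shared artifact).
    """
    runs = []
    for seed in range(20):
        outdir = tmp_path_factory.mktemp(f"recovery{seed}")
        summary = run_bsaseq(
            RunConfig(outdir=outdir, cross=default_config(), seed=seed, make_plots=False)
        )
        runs.append((summary, outdir))
    return runs


@pytest.fixture(scope="session")
def null_runs(tmp_path_factory):
    """20 seeded end-to-end runs of a cross with no causal loci."""
    cross = CrossConfig(
        chrom_lengths=default_config().chrom_lengths, causal_loci=()
    )
    runs = []
    for seed in range(20):
        outdir = tmp_path_factory.mktemp(f"null{seed}")
        summary = run_bsaseq(
            RunConfig(outdir=outdir, cross=cross, seed=seed, make_plots=False)
        )
        runs.append((summary, outdir))
    return runs
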