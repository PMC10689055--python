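import numpy as np
import pytest

from sweepscan.benchmark import popmap_for_matrix, run_sweep_benchmark
from sweepscan.genomic_io import PopulationMap, make_windows
from sweepscan.simulate import (
    GroupSpec,
    SimConfig,
    SweepSpec,
    simulate_genotypes,
    write_fixture_bundle,
)

BENCHMARK_SEEDS = (1, 2, 3, 4, 5)


def two_group_sim(drift_a, drift_b, n_diploids=30, genome_mb=25.5, seed=11, density=0.002):
    """Two-group Balding-Nichols panel for F_ST recovery checks."""
    cfg = SimConfig(
        groups=[GroupSpec("A", n_diploids, drift_a), GroupSpec("B", n_diploids, drift_b)],
        genome=[("chr1", int(genome_mb * 1e6))],
        snp_density=density,
        seed=seed,
    )
    matrix, _ = simulate_genotypes(cfg)
    return matrix, popmap_for_matrix(matrix), dict(cfg.genome)


def three_group_sim(drifts, n_diploids=30, genome_mb=15.0, seed=13, sweeps=()):
    cfg = SimConfig(
        groups=[GroupSpec(lbl, n_diploids, f) for lbl, f in zip(("A", "B", "C"), drifts)],
        genome=[("chr1", int(genome_mb * 1e6))],
        sweeps=list(sweeps),
        seed=seed,
    )
    matrix, truth = simulate_genotypes(cfg)
    return matrix, popmap_for_matrix(matrix), dict(cfg.genome), truth


@pytest.fixture(scope="session")
def small_sweep_sim():
    """Three groups, one planted 250-kb sweep on a 10-Mb chromosome."""
    cfg = SimConfig(
        groups=[GroupSpec("BG", 30, 0.1), GroupSpec("CG1", 30, 0.1), GroupSpec("G3", 30, 0.1)],
        genome=[("chr1", 10_000_000)],
        sweeps=[SweepSpec("CG1", "chr1", 5_000_000, 5_250_000, 0.95)],
        seed=7,
    )
    matrix, truth = simulate_genotypes(cfg)
    return matrix, popmap_for_matrix(matrix), dict(cfg.genome), truth


def toy_config(seed=3):
    """42-window two-chromosome fixture with one planted sweep and traits."""
    return SimConfig(
        groups=[GroupSpec("BG", 12, 0.1), GroupSpec("CG1", 12, 0.1), GroupSpec("G3", 12, 0.1)],
        genome=[("chr1", 3_000_000), ("chr2", 3_000_000)],
        sweeps=[SweepSpec("CG1", "chr1", 1_500_000, 1_750_000, 0.95)],
        seed=seed,
    )


@pytest.fixture(scope="session")
def toy_bundle(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("toy_fixture")
    truth = write_fixture_bundle(
        outdir,
        toy_config(),
        phenotype_spec=(None, 8.0, 2.0),
        expression_spec=("gene00003", -0.4),
    )
    return outdir, truth


@pytest.fixture(scope="session")
def benchmark_runs():
    """The planted-sweep benchmark scanned at five seeds."""
    return {seed: run_sweep_benchmark(seed) for seed in BENCHMARK_SEEDS}
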