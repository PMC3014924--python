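import numpy as np
import pytest

from lombkit import binning, lomb_calling
from lombkit.annotation import annotate_bins
from lombkit.genome_io import GeneModel, GenomeModel
from lombkit.synthetic_data import (
    SimConfig, asymmetry_config, benchmark_config, simulate,
)


def small_config(seed: int = 7, **overrides) -> SimConfig:
    """A fast single-chromosome simulation (~2,000 bins) for unit tests."""
    kwargs = dict(
        seed=seed, n_chromosomes=1, chrom_length=600_000, n_genes=20,
        gene_length_range=(1500, 3000), gene_min_gap=2500,
        het_fraction=0.15, n_target_genes=8,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def small_sim():
    return simulate(small_config())


@pytest.fixture(scope="session")
def benchmark_sim():
    """The fixed recovery benchmark: 50,000 euchromatic bins, depth 20,
    8-fold loss, 200 planted bins, seed 1."""
    return simulate(benchmark_config(seed=1))


@pytest.fixture(scope="session")
def benchmark_counts(benchmark_sim):
    counts = binning.count_samples(
        [benchmark_sim.tags_wt, benchmark_sim.tags_mt], benchmark_sim.grid)
    return binning.equalize_libraries(counts)


@pytest.fixture(scope="session")
def benchmark_lombs(benchmark_counts):
    ratios = lomb_calling.compute_log_ratios(benchmark_counts, "wt", "mt")
    return ratios, lomb_calling.call_lombs(ratios)


@pytest.fixture(scope="session")
def benchmark_annotation(benchmark_sim):
    return annotate_bins(benchmark_sim.grid, benchmark_sim.genes)


@pytest.fixture(scope="session")
def asymmetry_lombs():
    res = simulate(asymmetry_config(seed=1))
    counts = binning.equalize_libraries(
        binning.count_samples([res.tags_wt, res.tags_mt], res.grid))
    ratios = lomb_calling.compute_log_ratios(counts, "wt", "mt")
    return res, lomb_calling.call_lombs(ratios)


@pytest.fixture
def toy_genome():
    return GenomeModel([("chrA", 3000), ("chrB", 600)])


@pytest.fixture
def plus_gene():
    # the worked positional-zone example gene: [5000, 8000) on + strand
    return GeneModel("g1", "chrA", "+", 5000, 8000)


def random_gene_models(rng: np.random.Generator, n_genes: int,
                       chrom: str = "chr1", length: int = 100_000):
    """Random, possibly overlapping gene models for oracle comparisons."""
    genes = []
    for i in range(n_genes):
        start = int(rng.integers(0, length - 2000))
        end = start + int(rng.integers(200, 2000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"g{i:03d}", chrom, strand, start, min(end, length)))
    return genes
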