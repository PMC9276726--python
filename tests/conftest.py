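import numpy as np
import pytest

from sweepscan import (
    GenotypeMatrix,
    PopulationMap,
    SweepInterval,
    SweepSimConfig,
    simulate_genotypes,
)


def make_matrix(dosage, samples=None, chrom="1", positions=None, ref="A", alt="G"):
    """Build a GenotypeMatrix from a plain dosage array (rows = sites)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_sites, n_samples = dosage.shape
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    return GenotypeMatrix(
        np.full(n_sites, chrom, dtype=object),
        np.asarray(positions, dtype=np.int64),
        np.full(n_sites, ref, dtype=object),
        np.full(n_sites, alt, dtype=object),
        samples,
        dosage,
    )


@pytest.fixture
def two_pop_map():
    """25 + 25 diploids labelled XP / TT."""
    names = [f"XP_{i:02d}" for i in range(25)] + [f"TT_{i:02d}" for i in range(25)]
    return names, PopulationMap({n: n.split("_")[0] for n in names})


@pytest.fixture(scope="session")
def small_cohort():
    """One 5-Mb chromosome, 25+25 diploids, one 500-kb sweep at s=0.95."""
    cfg = SweepSimConfig(
        chrom_lengths={"1": 5_000_000},
        sweep_intervals=[SweepInterval("1", 2_000_001, 2_500_000, "XP", 0.95)],
        seed=11,
    )
    matrix, popmap, truth = simulate_genotypes(cfg)
    return cfg, matrix, popmap, truth


@pytest.fixture(scope="session")
def gene_fixture():
    from sweepscan import simulate_gene_models

    sweeps = [SweepInterval("1", 2_000_001, 2_500_000, "XP", 0.95)]
    gff_text, fasta, gmt = simulate_gene_models(
        {"1": 5_000_000, "2": 5_000_000}, n_genes=60, seed=3, sweep_intervals=sweeps
    )
    return gff_text, fasta, gmt, sweeps
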