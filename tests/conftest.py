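import numpy as np
import pandas as pd
import pytest

from droughtgwas.datatypes import GenomeSpec, GenotypeMatrix, SweepSpec, default_genome
from droughtgwas import simulate


@pytest.fixture(scope="session")
def small_genome() -> GenomeSpec:
    return default_genome(2, 2_000_000)


@pytest.fixture(scope="session")
def panel_genome() -> GenomeSpec:
    return default_genome(4, 10_000_000)


@pytest.fixture(scope="session")
def small_panel(small_genome):
    """A 100-accession panel with a planted sweep on B01."""
    sweep = SweepSpec("B01", 1_000_000, 1_100_000, fst_target=0.6)
    geno = simulate.simulate_genotypes(small_genome, 100, 1_000, sweep=sweep, seed=1)
    return geno, sweep


def make_genotypes(columns: np.ndarray, chrom="A01", positions=None, samples=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from an (accessions x snps) dosage array."""
    columns = np.asarray(columns, float)
    n, m = columns.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 1000
    if samples is None:
        samples = [f"S{i:03d}" for i in range(n)]
    sites = pd.DataFrame(
        {
            "chrom": chrom if isinstance(chrom, str) else list(chrom),
            "pos": list(positions),
            "id": [f"{c}_{p}" for c, p in zip([chrom] * m if isinstance(chrom, str) else chrom, positions)],
            "ref": "A",
            "alt": "T",
        }
    )
    return GenotypeMatrix(samples=list(samples), sites=sites, calls=columns)
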