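"""Shared data containers for the drought-tolerance panel pipeline.

All genomic coordinates are 1-based inclusive (VCF/GFF3 convention).
Genotypes are coded as alternate-allele dosage 0/1/2 with ``NaN`` for
missing calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = np.nan

SITE_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]
GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]
PHENOTYPE_COLUMNS = ["accession", "trait", "treatment", "environment", "replicate", "value"]


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome names and lengths (bp, 1-based inclusive coordinates)."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def contains(self, chrom: str, pos: int) -> bool:
        lengths = self.lengths
        return chrom in lengths and 1 <= pos <= lengths[chrom]


def default_genome(n_chroms: int = 4, chrom_length: int = 10_000_000) -> GenomeSpec:
    """An A/B-labelled toy genome in the Brassica naming style (A01.., B01..)."""
    half = (n_chroms + 1) // 2
    names = [f"A{i + 1:02d}" for i in range(half)] + [f"B{i + 1:02d}" for i in range(n_chroms - half)]
    return GenomeSpec(tuple((name, chrom_length) for name in names))


@dataclass(frozen=True)
class QTLSpec:
    """A planted causal locus: SNP position, variance fraction, target trait."""

    chrom: str
    pos: int
    effect_size: float
    affected_trait: str
    affected_treatments: frozenset[str] = frozenset({"M", "S"})

    def __post_init__(self) -> None:
        if not 0.0 <= self.effect_size < 1.0:
            raise ValueError(f"effect_size must be in [0, 1): got {self.effect_size}")


@dataclass(frozen=True)
class SweepSpec:
    """A planted differentiated region between two subpopulations."""

    chrom: str
    start: int
    end: int
    fst_target: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"sweep start {self.start} must precede end {self.end}")
        if not 0.0 <= self.fst_target <= 1.0:
            raise ValueError(f"fst_target must be in [0, 1]: got {self.fst_target}")


@dataclass(frozen=True)
class ModuleSpecSim:
    """Planted co-expression module structure for the expression simulator."""

    n_modules: int = 3
    genes_per_module: int = 100
    trait_correlation: float = 0.8
    noise_sd: float = 0.5
    n_background: int = 200

    def __post_init__(self) -> None:
        if self.n_modules < 0 or self.genes_per_module < 0 or self.n_background < 0:
            raise ValueError("module counts must be non-negative")
        if abs(self.trait_correlation) > 1:
            raise ValueError("|trait_correlation| must be <= 1")
        if self.n_modules > 0 and self.genes_per_module < 2:
            raise ValueError("a module needs at least 2 genes")


@dataclass
class GenotypeMatrix:
    """Accessions x biallelic SNPs, alt-dosage coded, with a site map.

    ``calls`` is float (n_accessions, n_snps): 0/1/2 dosage, NaN missing.
    ``sites`` has columns chrom, pos, id, ref, alt, sorted by (chrom, pos).
    """

    samples: list[str]
    sites: pd.DataFrame
    calls: np.ndarray
    subpop: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        missing = [c for c in SITE_COLUMNS if c not in self.sites.columns]
        if missing:
            raise ValueError(f"sites table lacks columns {missing}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per site, missing-aware."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.calls, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        if self.n_sites == 0:
            return np.empty(0)
        return 1.0 - np.isnan(self.calls).mean(axis=0)

    def site_index(self, chrom: str, pos: int) -> int:
        hit = np.flatnonzero((self.sites["chrom"].values == chrom) & (self.sites["pos"].values == pos))
        if hit.size == 0:
            raise KeyError(f"no SNP at {chrom}:{pos} in genotype map")
        return int(hit[0])

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.loc[mask].reset_index(drop=True),
            calls=self.calls[:, np.asarray(mask)],
            subpop=self.subpop,
        )

    def region_mask(self, chrom: str, start: int, end: int) -> np.ndarray:
        return (
            (self.sites["chrom"].values == chrom)
            & (self.sites["pos"].values >= start)
            & (self.sites["pos"].values <= end)
        )


@dataclass
class ExpressionMatrix:
    """Genes x samples FPKM-like values plus the sample design sheet."""

    values: pd.DataFrame  # index = gene ids, columns = sample ids
    design: pd.DataFrame  # columns: sample, tissue, treatment, group
    planted_modules: pd.Series | None = None  # gene -> planted module label

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        if list(self.values.columns) != list(self.design["sample"]):
            raise ValueError("expression columns must match design sample order")
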