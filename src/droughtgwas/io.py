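"""Readers and writers for the pipeline's on-disk formats.

VCF v4.2 (GT-only FORMAT) and gene-feature GFF3 are the genomic exchange
formats; phenotype, expression and design tables are plain TSV.  Reading
VCF goes through cyvcf2; writing emits text directly from the in-memory
matrix (headers carry ##contig lines when a :class:`GenomeSpec` is given).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import (
    GENE_COLUMNS,
    PHENOTYPE_COLUMNS,
    GenomeSpec,
    GenotypeMatrix,
    ExpressionMatrix,
)

_GT_CODES = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(geno: GenotypeMatrix, path: str | os.PathLike, genome: GenomeSpec | None = None) -> None:
    """Write a VCF v4.2 with a GT-only FORMAT field."""
    lines = ["##fileformat=VCFv4.2", "##source=droughtgwas"]
    if genome is not None:
        for name, length in genome.chromosomes:
            lines.append(f"##contig=<ID={name},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(geno.samples))
    sites = geno.sites
    calls = geno.calls
    for j in range(geno.n_sites):
        row = sites.iloc[j]
        gts = "\t".join(
            _GT_CODES.get(calls[i, j], "./.") if not np.isnan(calls[i, j]) else "./."
            for i in range(geno.n_samples)
        )
        lines.append(
            f"{row['chrom']}\t{int(row['pos'])}\t{row['id']}\t{row['ref']}\t{row['alt']}\t.\tPASS\t.\tGT\t{gts}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Load biallelic SNP genotypes from VCF as an alt-dosage matrix."""
    vcf = VCF(os.fspath(path), gts012=True)
    samples = list(vcf.samples)
    chroms, poss, ids, refs, alts = [], [], [], [], []
    columns = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            continue
        chroms.append(variant.CHROM)
        poss.append(variant.POS)
        ids.append(variant.ID or f"{variant.CHROM}_{variant.POS}")
        refs.append(variant.REF)
        alts.append(variant.ALT[0])
        g = variant.gt_types.astype(float)  # 0/1/2, 3 = unknown
        g[g == 3] = np.nan
        columns.append(g)
    vcf.close()
    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "id": ids, "ref": refs, "alt": alts})
    calls = np.column_stack(columns) if columns else np.empty((len(samples), 0))
    order = np.lexsort((sites["pos"].values, sites["chrom"].values))
    sites = sites.iloc[order].reset_index(drop=True)
    calls = calls[:, order] if calls.size else calls
    return GenotypeMatrix(samples=samples, sites=sites, calls=calls)


def write_gff3(annotation: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write gene features (1-based inclusive) as GFF3."""
    lines = ["##gff-version 3"]
    for _, row in annotation.iterrows():
        lines.append(
            "\t".join(
                [
                    str(row["chrom"]),
                    "droughtgwas",
                    "gene",
                    str(int(row["start"])),
                    str(int(row["end"])),
                    ".",
                    str(row.get("strand", "+")),
                    ".",
                    f"ID={row['gene_id']}",
                ]
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gff3(path: str | os.PathLike) -> pd.DataFrame:
    """Read gene features from GFF3 into the annotation table schema."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9 or parts[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
            rows.append(
                {
                    "gene_id": attrs.get("ID", f"{parts[0]}:{parts[3]}-{parts[4]}"),
                    "chrom": parts[0],
                    "start": int(parts[3]),
                    "end": int(parts[4]),
                    "strand": parts[6],
                }
            )
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def write_phenotypes(pheno: pd.DataFrame, path: str | os.PathLike) -> None:
    pheno[PHENOTYPE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | os.PathLike) -> pd.DataFrame:
    pheno = pd.read_csv(path, sep="\t", dtype={"accession": str, "environment": str})
    missing = [c for c in PHENOTYPE_COLUMNS if c not in pheno.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns {missing}")
    return pheno


def write_expression(expr: ExpressionMatrix, expr_path: str | os.PathLike, design_path: str | os.PathLike) -> None:
    expr.values.to_csv(expr_path, sep="\t", index_label="gene")
    expr.design.to_csv(design_path, sep="\t", index=False)


def read_expression(expr_path: str | os.PathLike, design_path: str | os.PathLike) -> ExpressionMatrix:
    values = pd.read_csv(expr_path, sep="\t", index_col="gene")
    design = pd.read_csv(design_path, sep="\t", dtype=str)
    return ExpressionMatrix(values=values, design=design)
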