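"""End-to-end orchestration: simulate -> score -> GWAS -> sweep -> coexpress
-> integrate -> haplotype, with all declared flat-file outputs.

This is the programmatic counterpart of chaining the CLI subcommands; the
acceptance script and the smoke test both drive it.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coexpression, fst, gwas, haplotype, integration, io, scoring, simulate
from .datatypes import GenomeSpec, ModuleSpecSim, QTLSpec, SweepSpec, default_genome


@dataclass
class PanelConfig:
    """Study-scale defaults for the synthetic panel (desk-scale rapeseed-like)."""

    n_accessions: int = 200
    n_snps: int = 5_000
    n_genes: int = 1_500
    genome: GenomeSpec = field(default_factory=lambda: default_genome(4, 10_000_000))
    qtl_effect: float = 0.15
    qtl_trait: str = "germination_rate"
    sweep_fst: float = 0.6
    heritability: float = 0.5
    module_spec: ModuleSpecSim = field(default_factory=ModuleSpecSim)


@dataclass
class PanelData:
    geno: object
    pheno: pd.DataFrame
    expr: object
    annotation: pd.DataFrame
    qtl: QTLSpec
    sweep: SweepSpec


def simulate_panel(config: PanelConfig | None = None, seed: int = 0) -> PanelData:
    """Generate a full coherent dataset with one planted QTL and one sweep."""
    cfg = config or PanelConfig()
    chrom_a = cfg.genome.names[0]
    chrom_b = cfg.genome.names[-1]
    length_b = cfg.genome.lengths[chrom_b]
    sweep = SweepSpec(
        chrom=chrom_b,
        start=int(length_b * 0.55),
        end=int(length_b * 0.58),
        fst_target=cfg.sweep_fst,
    )
    geno = simulate.simulate_genotypes(
        cfg.genome,
        n_accessions=cfg.n_accessions,
        n_snps=cfg.n_snps,
        sweep=sweep,
        seed=seed,
    )
    # Plant the QTL on an existing mid-chromosome SNP away from the sweep.
    on_a = geno.sites[geno.sites["chrom"] == chrom_a]
    target = cfg.genome.lengths[chrom_a] // 2
    qtl_row = on_a.iloc[(on_a["pos"] - target).abs().argmin()]
    qtl = QTLSpec(
        chrom=chrom_a,
        pos=int(qtl_row["pos"]),
        effect_size=cfg.qtl_effect,
        affected_trait=cfg.qtl_trait,
    )
    pheno = simulate.simulate_phenotypes(
        geno, qtls=[qtl], heritability=cfg.heritability, seed=seed + 1
    )
    design = simulate.default_sample_design()
    expr = simulate.simulate_expression(cfg.module_spec, design, seed=seed + 2)
    annotation = simulate.simulate_annotation(cfg.genome, cfg.n_genes, seed=seed + 3)
    return PanelData(geno=geno, pheno=pheno, expr=expr, annotation=annotation, qtl=qtl, sweep=sweep)


def run_pipeline(
    out_dir: str | os.PathLike,
    config: PanelConfig | None = None,
    seed: int = 0,
    trait: str = "germination_rate",
    environment: str = "E1",
    threshold_mode: str = "suggestive",
) -> dict:
    """Full pipeline on a simulated panel; writes every declared output file.

    Returns a summary dict of headline counts (significant SNPs, QTLs,
    tolerance classes, sweep regions, modules, candidate genes, haplotypes).
    """
    cfg = config or PanelConfig()
    os.makedirs(out_dir, exist_ok=True)
    data = simulate_panel(cfg, seed=seed)
    geno, pheno, expr, annotation = data.geno, data.pheno, data.expr, data.annotation

    io.write_vcf(geno, os.path.join(out_dir, "genotypes.vcf"), genome=cfg.genome)
    io.write_phenotypes(pheno, os.path.join(out_dir, "phenotypes.tsv"))
    io.write_gff3(annotation, os.path.join(out_dir, "genes.gff3"))
    io.write_expression(
        expr,
        os.path.join(out_dir, "expression.tsv"),
        os.path.join(out_dir, "sample_design.tsv"),
    )

    # --- scoring ---------------------------------------------------------
    scores = scoring.score_panel(pheno)
    scores.to_csv(os.path.join(out_dir, "d_values.tsv"), sep="\t", index=False)
    tr = scoring.relative_trait(pheno)
    tr.to_csv(os.path.join(out_dir, "relative_traits.tsv"), sep="\t", index=False)
    summary = scoring.descriptive_stats(
        scoring.relative_trait(pheno).rename(columns={"TR": "value"})
    )
    summary.to_csv(os.path.join(out_dir, "trait_summary.tsv"), sep="\t", index=False)

    # --- GWAS ------------------------------------------------------------
    tr_env = tr[(tr["trait"] == trait) & (tr["treatment"] == "M") & (tr["environment"] == environment)]
    trait_values = tr_env.set_index("accession")["TR"]
    K = gwas.kinship_matrix(geno)
    scan = gwas.emmax_scan(geno, trait_values, K=K)
    scan.to_csv(os.path.join(out_dir, f"scan_{trait}_{environment}.tsv"), sep="\t", index=False)
    cutoff = gwas.significance_threshold(int(scan["tested"].sum()), threshold_mode)
    sig = scan[(scan["tested"]) & (scan["p"] <= cutoff)]
    qtls = gwas.merge_snps_to_qtls(sig, geno)
    qtls.to_csv(os.path.join(out_dir, "qtls.tsv"), sep="\t", index=False)
    windows = gwas.candidate_gene_windows(sig, annotation, chrom_lengths=cfg.genome.lengths)
    windows.to_csv(os.path.join(out_dir, "candidate_windows.tsv"), sep="\t", index=False)

    # --- selective sweep -------------------------------------------------
    classes = scores.set_index("accession")["class"]
    group_a = list(classes[classes == "tolerant"].index)
    group_b = list(classes[classes == "sensitive"].index)
    sites = fst.per_site_fst(geno, group_a, group_b)
    sites.to_csv(os.path.join(out_dir, "fst_sites.tsv"), sep="\t", index=False)
    fst_windows = fst.windowed_fst(sites, chrom_lengths=cfg.genome.lengths)
    fst_windows.to_csv(os.path.join(out_dir, "fst_windows.tsv"), sep="\t", index=False)
    regions = fst.top_regions(fst_windows, 0.05)
    regions.to_csv(os.path.join(out_dir, "sweep_regions.tsv"), sep="\t", index=False)
    overlap = fst.intersect_with_gwas(regions, windows)
    overlap.to_csv(os.path.join(out_dir, "sweep_gwas_overlap.tsv"), sep="\t", index=False)

    # --- co-expression ---------------------------------------------------
    filtered = coexpression.filter_expression(expr)
    tom = coexpression.adjacency_tom(filtered.values, power=9)
    modules = coexpression.detect_modules(tom, filtered.values, min_module_size=50)
    modules.labels.rename("module").to_frame().to_csv(os.path.join(out_dir, "modules.tsv"), sep="\t", index_label="gene")
    modules.eigengenes.to_csv(os.path.join(out_dir, "eigengenes.tsv"), sep="\t", index_label="module")
    covariates = pd.get_dummies(filtered.design.set_index("sample")["treatment"]).astype(float)
    mt = coexpression.module_trait_correlation(modules.eigengenes, covariates)
    mt.to_csv(os.path.join(out_dir, "module_trait.tsv"), sep="\t", index=False)

    # --- integration -----------------------------------------------------
    significant_modules = sorted(set(mt[mt["stars"] != "NS"]["module"]))
    # The synthetic expression genes are not positioned on the genome; for
    # the integration join we map module genes onto annotation gene models
    # by rank so the interval logic is exercised end to end.
    gene_map = dict(zip(modules.labels.index, annotation["gene_id"]))
    mapped_labels = modules.labels.rename(index=gene_map)
    candidates = integration.module_gwas_overlap(
        mapped_labels, significant_modules, windows, annotation
    )
    candidates.to_csv(os.path.join(out_dir, "candidate_genes.tsv"), sep="\t", index=False)
    if len(sig):
        allele = integration.allele_association_table(
            geno, list(sig["id"].head(5)), trait_values
        )
        allele.to_csv(os.path.join(out_dir, "allele_assoc.tsv"), sep="\t", index=False)

    # --- haplotype region ------------------------------------------------
    # Case-study slice of the sweep (regional analyses target a sub-interval
    # of tens of kb, not the whole swept stretch).
    region = (data.sweep.chrom, data.sweep.start, min(data.sweep.start + 40_000, data.sweep.end))
    haps = haplotype.assign_haplotypes(geno, *region)
    haps.to_csv(os.path.join(out_dir, "haplotypes.tsv"), sep="\t", index=False)
    hap_classes = haplotype.haplotype_class_distribution(haps, classes)
    hap_classes.to_csv(os.path.join(out_dir, "hap_class_table.tsv"), sep="\t", index=False)
    assoc = haplotype.regional_association(geno, *region, trait_values)
    assoc.to_csv(os.path.join(out_dir, "regional_assoc.tsv"), sep="\t", index=False)

    class_counts = classes.value_counts()
    return {
        "n_accessions": geno.n_samples,
        "n_snps": geno.n_sites,
        "n_significant_snps": int(len(sig)),
        "n_qtls": int(len(qtls)),
        "n_tolerant": int(class_counts.get("tolerant", 0)),
        "n_medium": int(class_counts.get("medium", 0)),
        "n_sensitive": int(class_counts.get("sensitive", 0)),
        "n_sweep_regions": int(len(regions)),
        "n_modules": int(len(modules.sizes)),
        "n_significant_modules": len(significant_modules),
        "n_candidate_genes": int(candidates["gene_id"].nunique()) if len(candidates) else 0,
        "n_haplotypes": int(len(haps)),
        "sweep_recovered": bool(
            (
                (regions["chrom"] == data.sweep.chrom)
                & (regions["start"] <= data.sweep.end)
                & (regions["end"] >= data.sweep.start)
            ).any()
        ),
        "qtl_chrom": data.qtl.chrom,
        "qtl_pos": data.qtl.pos,
    }
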