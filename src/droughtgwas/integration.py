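"""Joint GWAS x co-expression candidate-gene calling and allele tests.

Two joins close the pipeline: genes lying in a significant SNP's candidate
window that also belong to a significantly trait-correlated co-expression
module become candidate genes (one row per gene x SNP pair, duplicates
retained); and each candidate SNP's genotype classes (hom-ref / het /
hom-alt, missing reported separately) are tested against a phenotype with
Welch's test (2 classes) or one-way ANOVA (>= 3).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats


def _stars(p: float) -> str:
    if np.isnan(p):
        return "NS"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "NS"


def module_gwas_overlap(
    module_labels: pd.Series,
    significant_modules: list[str],
    windows: pd.DataFrame,
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Genes inside candidate SNP windows that sit in significant modules.

    ``module_labels`` maps gene -> module; ``significant_modules`` is the
    user-supplied list of modules whose trait correlation reached at least
    one star.  A row is emitted per (gene, SNP window) pair, so one gene hit
    by several SNP windows appears several times.
    """
    ann_genes = set(annotation["gene_id"])
    labelled = set(module_labels.index)
    if labelled and len(labelled & ann_genes) / max(len(labelled), 1) < 0.5:
        raise ValueError(
            "less than half of module genes found in the annotation; "
            "likely mismatched gene identifiers"
        )
    keep = set(significant_modules) - {"grey"}
    ann = annotation.set_index("gene_id")
    rows = []
    for _, win in windows.iterrows():
        for gene in str(win.get("genes", "")).split(","):
            if not gene or gene not in ann.index:
                continue
            module = module_labels.get(gene, None)
            if module is None or module not in keep:
                continue
            g = ann.loc[gene]
            # Re-verify the interval overlap: every emitted row must be
            # derivable by pure interval arithmetic.
            if g["start"] > win["window_end"] or g["end"] < win["window_start"]:
                continue
            rows.append(
                {
                    "gene_id": gene,
                    "module": module,
                    "snp_id": win["snp_id"],
                    "chrom": win["chrom"],
                    "window_start": int(win["window_start"]),
                    "window_end": int(win["window_end"]),
                    "gene_start": int(g["start"]),
                    "gene_end": int(g["end"]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "module", "snp_id", "chrom",
            "window_start", "window_end", "gene_start", "gene_end",
        ],
    )


GENOTYPE_CLASS = {0.0: "hom_ref", 1.0: "het", 2.0: "hom_alt"}


def allele_phenotype_association(
    geno,
    snp_id: str,
    trait: pd.Series,
    min_class_size: int = 2,
) -> dict:
    """Test a SNP's genotype classes against a per-accession phenotype.

    Returns class sizes and trait means (missing genotypes reported as their
    own class but never tested), the test used, p and star code.  Classes
    smaller than ``min_class_size`` are reported but excluded from testing;
    fewer than 2 testable classes yields an NS result with a warning.
    """
    hit = np.flatnonzero(geno.sites["id"].values == snp_id)
    if hit.size == 0:
        raise KeyError(f"SNP {snp_id!r} not in genotype matrix")
    g = geno.calls[:, int(hit[0])]
    trait = trait.reindex(geno.samples)
    y = trait.to_numpy(float)
    if np.isnan(g).all():
        raise ValueError(f"all genotypes missing at {snp_id}")

    classes: dict[str, np.ndarray] = {}
    for code, name in GENOTYPE_CLASS.items():
        sel = (g == code) & ~np.isnan(y)
        if sel.any():
            classes[name] = y[sel]
    n_missing = int(np.isnan(g).sum())

    summary = {
        name: {"n": int(v.size), "mean": float(v.mean())} for name, v in classes.items()
    }
    summary["missing"] = {"n": n_missing, "mean": float(np.nanmean(y[np.isnan(g)])) if n_missing and not np.isnan(y[np.isnan(g)]).all() else np.nan}

    testable = {k: v for k, v in classes.items() if v.size >= min_class_size}
    if len(testable) < 2:
        warnings.warn(f"{snp_id}: fewer than 2 testable genotype classes; NS reported")
        p = np.nan
        test = "none"
    elif len(testable) == 2:
        a, b = testable.values()
        _, p = stats.ttest_ind(a, b, equal_var=False)
        test = "welch"
    else:
        _, p = stats.f_oneway(*testable.values())
        test = "anova"
    return {
        "snp_id": snp_id,
        "classes": summary,
        "tested_classes": sorted(testable),
        "test": test,
        "p": float(p) if not np.isnan(p) else np.nan,
        "significance": _stars(p),
    }


def allele_association_table(geno, snp_ids: list[str], trait: pd.Series, **kw) -> pd.DataFrame:
    """Flat table of allele-phenotype tests over several SNPs."""
    rows = []
    for snp_id in snp_ids:
        res = allele_phenotype_association(geno, snp_id, trait, **kw)
        row = {
            "snp_id": snp_id,
            "test": res["test"],
            "p": res["p"],
            "significance": res["significance"],
        }
        for name, cell in res["classes"].items():
            row[f"n_{name}"] = cell["n"]
            row[f"mean_{name}"] = cell["mean"]
        rows.append(row)
    return pd.DataFrame(rows)
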