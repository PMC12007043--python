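"""Regional LD, association and haplotype analysis of a genomic interval.

The region of interest (e.g. a jointly GWAS/sweep-supported interval) is
analysed four ways: a pairwise LD matrix (genotypic r^2 plus D' from
EM-estimated two-locus haplotype frequencies), a single-marker fixed-effects
association scan at a regional -log10(p) threshold (default 2.5), exact
grouping of unphased genotype strings (0/0, 0/1, 1/1 per SNP) into
haplotypes numbered by descending carrier count, and a haplotype x
tolerance-class contingency summary with exclusivity flags.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gwas import ld_r2

GT_STRING = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def genotype_loglik(counts: np.ndarray, f: np.ndarray) -> float:
    """Multinomial log-likelihood of a 3x3 two-SNP genotype table under
    random union of gametes with haplotype frequencies (AB, Ab, aB, ab)."""
    # Haplotypes indexed by (alt dosage at SNP1, alt dosage at SNP2):
    # AB = (0,0), Ab = (0,1), aB = (1,0), ab = (1,1) where A/B are the
    # reference alleles.
    haps = [(0, 0), (0, 1), (1, 0), (1, 1)]
    probs = np.zeros((3, 3))
    for x, (a1, b1) in enumerate(haps):
        for yy, (a2, b2) in enumerate(haps):
            probs[a1 + a2, b1 + b2] += f[x] * f[yy]
    with np.errstate(divide="ignore"):
        ll = np.where(counts > 0, counts * np.log(np.clip(probs, 1e-300, None)), 0.0)
    return float(ll.sum())


def em_haplotype_freqs(
    g1: np.ndarray,
    g2: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
    return_trace: bool = False,
):
    """EM haplotype frequencies (AB, Ab, aB, ab) for two unphased SNPs.

    Input dosage vectors over shared non-missing accessions.  Only the
    double-heterozygote class is phase-ambiguous; EM splits it by the current
    coupling/repulsion odds.  The log-likelihood is non-decreasing; iteration
    stops at ``tol`` change in frequencies or ``max_iter``.
    """
    ok = ~np.isnan(g1) & ~np.isnan(g2)
    g1, g2 = g1[ok].astype(int), g2[ok].astype(int)
    n = g1.size
    if n == 0:
        empty = np.full(4, np.nan)
        return (empty, []) if return_trace else empty
    counts = np.zeros((3, 3))
    for a, b in zip(g1, g2):
        counts[a, b] += 1

    pA = 1.0 - g1.mean() / 2.0  # freq of reference allele at SNP 1
    pB = 1.0 - g2.mean() / 2.0
    f = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    f = np.clip(f, 1e-12, None)
    f /= f.sum()

    n_dh = counts[1, 1]  # double heterozygotes
    # Unambiguous haplotype counts from the other 8 genotype classes:
    # genotype (i, j) contributes (2-i, 2-j) copies of allele A/B haplotypes.
    base = np.zeros(4)
    for i in range(3):
        for j in range(3):
            if i == 1 and j == 1:
                continue
            c = counts[i, j]
            if c == 0:
                continue
            nA, na = 2 - i, i
            nB, nb = 2 - j, j
            # haplotypes are determined: (A,B) copies = min distribution —
            # for single-het classes the phase is known because one locus is
            # homozygous.
            if i == 0:
                base[0] += c * nB
                base[1] += c * nb
            elif i == 2:
                base[2] += c * nB
                base[3] += c * nb
            elif j == 0:
                base[0] += c * nA
                base[2] += c * na
            else:  # j == 2
                base[1] += c * nA
                base[3] += c * na

    trace = []
    for _ in range(max_iter):
        coupling = f[0] * f[3]
        repulsion = f[1] * f[2]
        total = coupling + repulsion
        share = coupling / total if total > 0 else 0.5
        new = base.copy()
        new[0] += n_dh * share
        new[3] += n_dh * share
        new[1] += n_dh * (1.0 - share)
        new[2] += n_dh * (1.0 - share)
        new /= new.sum()
        if return_trace:
            trace.append(genotype_loglik(counts, new))
        if np.abs(new - f).max() < tol:
            f = new
            break
        f = new
    return (f, trace) if return_trace else f


def d_prime(freqs: np.ndarray) -> float:
    """Lewontin's D' from haplotype frequencies (AB, Ab, aB, ab)."""
    pAB, pAb, paB, pab = freqs
    pA = pAB + pAb
    pB = pAB + paB
    D = pAB - pA * pB
    if D >= 0:
        dmax = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        dmax = min(pA * pB, (1 - pA) * (1 - pB))
    if dmax == 0:
        return np.nan
    return float(D / dmax)


@dataclass
class RegionalLD:
    sites: pd.DataFrame
    r2: pd.DataFrame
    dprime: pd.DataFrame


def regional_ld(geno, chrom: str, start: int, end: int) -> RegionalLD:
    """Pairwise r^2 and D' matrices for the SNPs of a region."""
    mask = geno.region_mask(chrom, start, end)
    sub = geno.subset_sites(mask)
    maf = sub.maf()
    poly = maf > 0
    sub = sub.subset_sites(poly)
    if sub.n_sites < 2:
        raise ValueError(f"region {chrom}:{start}-{end} holds fewer than 2 polymorphic SNPs")
    ids = list(sub.sites["id"])
    m = sub.n_sites
    r2 = np.eye(m)
    dp = np.eye(m)
    for i, j in itertools.combinations(range(m), 2):
        r2[i, j] = r2[j, i] = ld_r2(sub, i, j)
        freqs = em_haplotype_freqs(sub.calls[:, i], sub.calls[:, j])
        dp[i, j] = dp[j, i] = d_prime(freqs)
    return RegionalLD(
        sites=sub.sites.copy(),
        r2=pd.DataFrame(r2, index=ids, columns=ids),
        dprime=pd.DataFrame(dp, index=ids, columns=ids),
    )


def regional_association(
    geno,
    chrom: str,
    start: int,
    end: int,
    trait: pd.Series,
    threshold_neglog10p: float = 2.5,
    min_maf: float = 0.0,
) -> pd.DataFrame:
    """Single-marker fixed-effects scan of the region (no kinship term).

    Each polymorphic SNP is tested by simple linear regression of the trait
    on dosage; SNPs with -log10(p) >= threshold are flagged.
    """
    mask = geno.region_mask(chrom, start, end)
    sub = geno.subset_sites(mask)
    trait = trait.reindex(geno.samples)
    y_all = trait.to_numpy(float)
    rows = []
    for j in range(sub.n_sites):
        g = sub.calls[:, j]
        ok = ~np.isnan(g) & ~np.isnan(y_all)
        g_ok, y_ok = g[ok], y_all[ok]
        p_freq = g_ok.mean() / 2.0 if g_ok.size else np.nan
        maf = min(p_freq, 1 - p_freq) if np.isfinite(p_freq) else 0.0
        if ok.sum() < 4 or g_ok.std() == 0 or y_ok.std() == 0 or maf < min_maf:
            rows.append({**sub.sites.iloc[j][["chrom", "pos", "id"]].to_dict(), "beta": np.nan, "p": np.nan, "neglog10p": np.nan, "flagged": False})
            continue
        res = stats.linregress(g_ok, y_ok)
        nlp = -np.log10(res.pvalue) if res.pvalue > 0 else np.inf
        rows.append(
            {
                **sub.sites.iloc[j][["chrom", "pos", "id"]].to_dict(),
                "beta": res.slope,
                "p": res.pvalue,
                "neglog10p": nlp,
                "flagged": bool(nlp >= threshold_neglog10p),
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "pos", "id", "beta", "p", "neglog10p", "flagged"])


def assign_haplotypes(
    geno, chrom: str, start: int, end: int, max_missing_frac: float = 0.1
) -> pd.DataFrame:
    """Group accessions by their exact regional genotype string.

    Strings use the 0/0, 0/1, 1/1 coding (0/0 = identical to the reference
    genome) joined by '-'; missing calls render as './.' and must match
    exactly for two accessions to share a haplotype.  Accessions with more
    than ``max_missing_frac`` missing calls in the region are excluded with
    a logged list.  Groups are numbered Hap1, Hap2, ... by descending
    carrier count (ties broken by lexicographic string).
    """
    mask = geno.region_mask(chrom, start, end)
    sub = geno.subset_sites(mask)
    if sub.n_sites == 0:
        raise ValueError(f"region {chrom}:{start}-{end} holds no SNPs")
    strings = []
    missing_frac = np.isnan(sub.calls).mean(axis=1)
    excluded = [s for s, f in zip(sub.samples, missing_frac) if f > max_missing_frac]
    if excluded:
        warnings.warn(f"excluded {len(excluded)} accessions over missing-call threshold: {excluded[:5]}...")
    for i, sample in enumerate(sub.samples):
        if missing_frac[i] > max_missing_frac:
            continue
        s = "-".join(
            GT_STRING.get(sub.calls[i, j], "./.") if not np.isnan(sub.calls[i, j]) else "./."
            for j in range(sub.n_sites)
        )
        strings.append((sample, s))
    groups: dict[str, list[str]] = {}
    for sample, s in strings:
        groups.setdefault(s, []).append(sample)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    rows = [
        {
            "haplotype": f"Hap{i + 1}",
            "genotype_string": s,
            "n_carriers": len(carriers),
            "carriers": ",".join(carriers),
        }
        for i, (s, carriers) in enumerate(ordered)
    ]
    out = pd.DataFrame(rows, columns=["haplotype", "genotype_string", "n_carriers", "carriers"])
    out.attrs["excluded"] = excluded
    return out


def haplotype_class_distribution(
    haplotypes: pd.DataFrame, classes: pd.Series
) -> pd.DataFrame:
    """Haplotype x tolerance-class contingency table with exclusivity flags.

    ``classes`` maps accession -> class label; carriers without a label are
    counted in an ``unclassified`` column with a warning.  A haplotype whose
    carriers all share one class gets that class as its ``exclusive_to``
    flag.
    """
    class_names = sorted(classes.dropna().unique())
    rows = []
    n_unlabelled = 0
    for _, hap in haplotypes.iterrows():
        carriers = hap["carriers"].split(",")
        counts = dict.fromkeys(class_names, 0)
        unclassified = 0
        for acc in carriers:
            label = classes.get(acc, None)
            if label is None or (isinstance(label, float) and np.isnan(label)):
                unclassified += 1
            else:
                counts[label] += 1
        n_unlabelled += unclassified
        nonzero = [k for k, v in counts.items() if v > 0]
        exclusive = nonzero[0] if len(nonzero) == 1 and unclassified == 0 else ""
        row = {"haplotype": hap["haplotype"], "n_carriers": hap["n_carriers"], **counts}
        row["unclassified"] = unclassified
        row["exclusive_to"] = exclusive
        for k in class_names:
            row[f"pct_{k}"] = 100.0 * counts[k] / hap["n_carriers"]
        rows.append(row)
    if n_unlabelled:
        warnings.warn(f"{n_unlabelled} haplotype carriers lack a tolerance class")
    return pd.DataFrame(rows)
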