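"""Weir-Cockerham Fst between tolerant and sensitive groups, windowed scan.

Per-site variance components a (among populations), b (among individuals
within populations) and c (within individuals) follow Weir & Cockerham
(1984) for two alleles, r = 2 populations of unequal size, diploid
heterozygote-aware counts.  The windowed statistic is the ratio of sums
(weighted Fst = sum a / sum (a+b+c)) over a 100 kb window advanced in 10 kb
steps, the convention of the common VCF Fst tools.  The top 5% of windows,
merged where they overlap, are called sweep regions.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd


def _wc_components(
    n_i: np.ndarray, p_i: np.ndarray, h_i: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Weir-Cockerham (1984) a, b, c for r populations per site.

    Arrays are (r, n_sites): per-population sample sizes (individuals),
    alternate-allele frequencies and observed heterozygote frequencies.
    """
    r = n_i.shape[0]
    n_bar = n_i.mean(axis=0)
    n_c = (r * n_bar - (n_i**2).sum(axis=0) / (r * n_bar)) / (r - 1)
    p_bar = (n_i * p_i).sum(axis=0) / (r * n_bar)
    s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (n_i * h_i).sum(axis=0) / (r * n_bar)

    with np.errstate(divide="ignore", invalid="ignore"):
        a = (n_bar / n_c) * (
            s2 - (1.0 / (n_bar - 1.0)) * (p_bar * (1.0 - p_bar) - ((r - 1.0) / r) * s2 - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1.0 - p_bar) - ((r - 1.0) / r) * s2 - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
        )
    c = h_bar / 2.0
    return a, b, c


def per_site_fst(geno, group_a: list[str], group_b: list[str]) -> pd.DataFrame:
    """Per-SNP Weir-Cockerham components and Fst = a / (a + b + c).

    Groups are disjoint accession lists.  Sites with fewer than 2 non-missing
    genotypes in either group, or monomorphic across both groups, are flagged
    ``informative = False`` with NaN Fst (their denominator contributes
    nothing to windowed sums).
    """
    set_a, set_b = set(group_a), set(group_b)
    if set_a & set_b:
        raise ValueError(f"groups overlap: {sorted(set_a & set_b)}")
    pos_of = {s: i for i, s in enumerate(geno.samples)}
    ia = [pos_of[s] for s in group_a]
    ib = [pos_of[s] for s in group_b]
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("each group needs at least 2 accessions")

    comps = []
    for rows in (ia, ib):
        G = geno.calls[rows, :]
        ok = ~np.isnan(G)
        n = ok.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.nansum(G, axis=0) / (2.0 * n)
            h = (G == 1).sum(axis=0) / n
        comps.append((n, p, h))
    n_i = np.vstack([c[0] for c in comps])
    p_i = np.vstack([c[1] for c in comps])
    h_i = np.vstack([c[2] for c in comps])

    valid = (n_i >= 2).all(axis=0)
    poly = valid.copy()
    with np.errstate(invalid="ignore"):
        pooled = np.where(valid, (n_i * p_i).sum(axis=0) / n_i.sum(axis=0), np.nan)
    poly &= (pooled > 0) & (pooled < 1)

    a = np.full(geno.n_sites, np.nan)
    b = np.full(geno.n_sites, np.nan)
    c = np.full(geno.n_sites, np.nan)
    if valid.any():
        av, bv, cv = _wc_components(n_i[:, valid], p_i[:, valid], h_i[:, valid])
        a[valid], b[valid], c[valid] = av, bv, cv

    denom = a + b + c
    informative = poly & np.isfinite(denom) & (denom != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(informative, a / denom, np.nan)

    out = geno.sites[["chrom", "pos", "id"]].copy()
    out["a"] = np.where(poly, a, np.nan)
    out["denominator"] = np.where(poly, denom, np.nan)
    out["fst"] = fst
    out["informative"] = informative
    return out


def window_starts(length: int, window: int, step: int) -> np.ndarray:
    """Window start positions 1, 1+step, ... fully inside a chromosome.

    For length >= window this yields floor((length - window) / step) + 1
    starts; a chromosome shorter than one window gets a single clipped
    window at position 1.
    """
    if length < window:
        return np.array([1], dtype=int)
    last = length - window + 1
    return np.arange(1, last + 1, step, dtype=int)


def windowed_fst(
    sites: pd.DataFrame,
    window: int = 100_000,
    step: int = 10_000,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Sliding-window weighted Fst (ratio of sums) over per-site components.

    Windows start at 1, 1 + step, 1 + 2*step, ... per chromosome (the full
    grid when chromosome lengths are given, else up to the last SNP);
    windows holding no informative SNP are omitted.  Negative per-site
    components are retained in the sums (estimator convention).
    """
    if step > window:
        warnings.warn(f"step {step} exceeds window {window}; coverage gaps possible")
    rows = []
    informative = sites[sites["informative"].fillna(False)]
    for chrom, grp in informative.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy(int)
        a = grp["a"].to_numpy(float)
        denom = grp["denominator"].to_numpy(float)
        fst = grp["fst"].to_numpy(float)
        if pos.size == 0:
            continue
        length = (
            chrom_lengths[chrom]
            if chrom_lengths and chrom in chrom_lengths
            else int(pos.max()) + window - 1
        )
        for start in window_starts(length, window, step):
            end = min(start + window - 1, length)
            sel = (pos >= start) & (pos <= end)
            if not sel.any():
                continue
            d = denom[sel].sum()
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(start),
                    "end": int(end),
                    "n_snps": int(sel.sum()),
                    "weighted_fst": a[sel].sum() / d if d != 0 else np.nan,
                    "mean_fst": float(np.mean(fst[sel])),
                }
            )
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "weighted_fst", "mean_fst"])
    return out.dropna(subset=["weighted_fst"]).reset_index(drop=True)


def top_regions(windows: pd.DataFrame, fraction: float = 0.05) -> pd.DataFrame:
    """Merge the top-``fraction`` windows by weighted Fst into sweep regions.

    ceil(fraction * N) windows are flagged; overlapping or bookended flagged
    windows on a chromosome merge into maximal regions carrying the peak
    window's statistic.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1]: got {fraction}")
    if windows.empty:
        raise ValueError("no windows to rank")
    n_top = math.ceil(fraction * len(windows))
    flagged = windows.sort_values("weighted_fst", ascending=False, kind="stable").head(n_top)
    flagged = flagged.sort_values(["chrom", "start"])

    regions = []
    for _, row in flagged.iterrows():
        if (
            regions
            and regions[-1]["chrom"] == row["chrom"]
            and row["start"] <= regions[-1]["end"] + 1
        ):
            reg = regions[-1]
            reg["end"] = max(reg["end"], int(row["end"]))
            reg["n_windows"] += 1
            if row["weighted_fst"] > reg["peak_fst"]:
                reg["peak_fst"] = float(row["weighted_fst"])
                reg["peak_start"] = int(row["start"])
        else:
            regions.append(
                {
                    "chrom": row["chrom"],
                    "start": int(row["start"]),
                    "end": int(row["end"]),
                    "n_windows": 1,
                    "peak_fst": float(row["weighted_fst"]),
                    "peak_start": int(row["start"]),
                }
            )
    out = pd.DataFrame(regions, columns=["chrom", "start", "end", "n_windows", "peak_fst", "peak_start"])
    out.insert(0, "region_id", [f"SW{i + 1:03d}" for i in range(len(out))])
    out.attrs["n_flagged"] = n_top
    return out


def intersect_with_gwas(regions: pd.DataFrame, windows: pd.DataFrame) -> pd.DataFrame:
    """Overlap sweep regions with GWAS candidate-gene windows.

    Each (region, SNP window) pair overlapping by >= 1 bp is reported with
    the genes of the SNP window that fall inside the intersection interval.
    The gene coordinate columns, when present in ``windows`` (as emitted by
    pairing candidate windows with an annotation), restrict genes to the
    intersection; otherwise the SNP window's gene list is passed through.
    """
    rows = []
    for _, reg in regions.iterrows():
        for _, win in windows.iterrows():
            if reg["chrom"] != win["chrom"]:
                continue
            start = max(int(reg["start"]), int(win["window_start"]))
            end = min(int(reg["end"]), int(win["window_end"]))
            if start > end:
                continue
            rows.append(
                {
                    "region_id": reg.get("region_id", f"{reg['chrom']}:{reg['start']}"),
                    "chrom": reg["chrom"],
                    "region_start": int(reg["start"]),
                    "region_end": int(reg["end"]),
                    "snp_id": win["snp_id"],
                    "overlap_start": start,
                    "overlap_end": end,
                    "genes": win.get("genes", ""),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "region_id", "chrom", "region_start", "region_end",
            "snp_id", "overlap_start", "overlap_end", "genes",
        ],
    )


def intersect_genes(
    overlap: pd.DataFrame, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Restrict each overlap row's gene list to genes inside the intersection."""
    ann = annotation.set_index("gene_id")
    kept = []
    for _, row in overlap.iterrows():
        genes = [g for g in str(row["genes"]).split(",") if g]
        inside = [
            g
            for g in genes
            if g in ann.index
            and ann.loc[g, "start"] <= row["overlap_end"]
            and ann.loc[g, "end"] >= row["overlap_start"]
        ]
        kept.append(",".join(inside))
    out = overlap.copy()
    out["genes"] = kept
    return out
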