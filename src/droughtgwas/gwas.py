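"""Kinship-corrected single-marker association scan and QTL integration.

The association model is the two-stage mixed-model approximation popularized
as EMMAX: variance components of  y = Xb + g + e,  g ~ N(0, sg^2 K),
e ~ N(0, se^2 I)  are estimated once by REML under the null (intercept-only)
model via the eigendecomposition of the kinship matrix K, after which each
SNP is tested by generalized least squares with the variance ratio held
fixed.  K is the VanRaden genomic relationship matrix.  Significant SNPs are
chained into QTLs under a distance (<= 100 kb) + LD (r^2 > 0.35) rule, and
candidate genes are collected from +/-100 kb windows around each SNP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


# ---------------------------------------------------------------------------
# Kinship


def kinship_matrix(geno) -> np.ndarray:
    """VanRaden genomic relationship matrix.

    Missing genotypes are mean-imputed; dosages are centred at 2p and the
    cross-product is scaled by 2 * sum p(1-p) over polymorphic SNPs.
    """
    X = geno.calls.copy()
    if X.shape[1] == 0:
        raise ValueError("no SNPs available for kinship")
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    p = col_mean / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic SNPs available for kinship")
    Z = X[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    return (Z @ Z.T) / denom


# ---------------------------------------------------------------------------
# EMMAX-style scan


def _reml_delta(y: np.ndarray, eigvals: np.ndarray, U: np.ndarray) -> float:
    """REML estimate of delta = se^2/sg^2 for the intercept-only null model.

    Works in the rotated basis of K's eigenvectors; the intercept is
    projected out first (restricted likelihood), then the profile REML
    criterion in log10(delta) is minimized by grid + Brent refinement.
    """
    n = y.size
    one = np.ones((n, 1))
    # Residual-forming rotation: eigendecompose the projected kinship.
    P = np.eye(n) - one @ one.T / n
    PKP = P @ (U * eigvals) @ U.T @ P
    lam, Q = np.linalg.eigh(PKP)
    lam = lam[1:]  # drop the null direction of the projection
    Q = Q[:, 1:]
    eta = Q.T @ y
    lam = np.clip(lam, 0.0, None)

    def neg_reml(log_delta: float) -> float:
        delta = 10.0 ** log_delta
        w = lam + delta
        sg2 = np.mean(eta**2 / w)
        if sg2 <= 0:
            return np.inf
        return ((n - 1) * np.log(sg2) + np.log(w).sum()) / 2.0

    grid = np.linspace(-6.0, 6.0, 25)
    vals = [neg_reml(g) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg_reml, bounds=(lo, hi), method="bounded")
    return float(10.0 ** res.x)


def emmax_scan(
    geno,
    trait: pd.Series,
    K: np.ndarray | None = None,
    min_maf: float = 0.05,
    min_call_rate: float = 0.9,
) -> pd.DataFrame:
    """Mixed-model association scan of one trait against every SNP.

    ``trait`` is indexed by accession.  SNPs failing the MAF or call-rate
    filter are reported with ``tested = False`` and NaN statistics; missing
    genotypes are mean-imputed before testing.  Returns one row per SNP with
    beta, se, t statistic, p and -log10(p).
    """
    trait = trait.reindex(geno.samples)
    keep = trait.notna().to_numpy()
    y = trait.to_numpy(float)[keep]
    n = y.size
    if n <= 3:
        raise ValueError("need more than 3 phenotyped accessions")
    if np.ptp(y) == 0:
        raise ValueError("trait is constant")
    if K is None:
        K = kinship_matrix(geno)
    K = np.asarray(K, float)[np.ix_(keep, keep)]
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("kinship matrix is not symmetric")
    eigvals, U = np.linalg.eigh(K)
    if eigvals.min() < -1e-6:
        raise ValueError("kinship matrix is not PSD within tolerance")
    eigvals = np.clip(eigvals, 0.0, None)

    delta = _reml_delta(y, eigvals, U)
    w = 1.0 / np.sqrt(eigvals + delta)  # whitening weights in the rotated basis

    yt = w * (U.T @ y)
    ones_t = w * (U.T @ np.ones(n))

    X = geno.calls[keep, :].copy()
    maf = geno.maf()
    call_rate = geno.call_rate()
    col_mean = np.nanmean(X, axis=0) if X.size else np.empty(0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])

    tested = (maf >= min_maf) & (call_rate >= min_call_rate)
    Xt = (U.T @ X) * w[:, None]

    # Per-SNP GLS with intercept, vectorized via 2x2 normal equations.
    s00 = ones_t @ ones_t
    s01 = ones_t @ Xt
    s11 = np.einsum("ij,ij->j", Xt, Xt)
    b0y = ones_t @ yt
    b1y = Xt.T @ yt
    det = s00 * s11 - s01**2
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (s00 * b1y - s01 * b0y) / det
        alpha = (s11 * b0y - s01 * b1y) / det
        rss = (yt @ yt) - alpha * b0y - beta * b1y
        df = n - 2
        sigma2 = rss / df
        se = np.sqrt(sigma2 * s00 / det)
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    degenerate = ~np.isfinite(tstat)
    tested &= ~degenerate

    out = geno.sites.copy()
    out["maf"] = maf
    out["call_rate"] = call_rate
    out["tested"] = tested
    for col, arr in [("beta", beta), ("se", se), ("t", tstat), ("p", p)]:
        a = np.where(tested, arr, np.nan)
        out[col] = a
    out["neglog10p"] = -np.log10(out["p"])
    out.attrs["delta"] = delta
    out.attrs["n"] = n
    return out


def significance_threshold(n_snps: int, mode: str = "bonferroni") -> float:
    """P-value cutoff: Bonferroni 0.05/n, or the suggestive 1e-4 line."""
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if mode == "bonferroni":
        return 0.05 / n_snps
    if mode == "suggestive":
        return 1e-4
    raise ValueError(f"unknown threshold mode {mode!r}")


def co_detected(
    scans: dict[str, pd.DataFrame],
    threshold: float,
    min_envs: int = 2,
) -> pd.DataFrame:
    """SNPs significant in at least ``min_envs`` environment scans.

    SNPs are matched by (chrom, pos).  Returns the matched SNPs with the set
    of environments in which each was significant.
    """
    if len(scans) < 2:
        raise ValueError("need scans from at least 2 environments")
    universes = [set(zip(s["chrom"], s["pos"])) for s in scans.values()]
    shared = set.intersection(*universes)
    if not shared:
        raise ValueError("environment scans have disjoint SNP universes")
    hits: dict[tuple, list[str]] = {}
    for env, scan in scans.items():
        sig = scan[(scan["tested"]) & (scan["p"] <= threshold)]
        for key in zip(sig["chrom"], sig["pos"]):
            hits.setdefault(key, []).append(env)
    rows = [
        {"chrom": c, "pos": p, "id": f"{c}_{p}", "environments": ",".join(sorted(envs)), "n_envs": len(envs)}
        for (c, p), envs in hits.items()
        if len(envs) >= min_envs
    ]
    out = pd.DataFrame(rows, columns=["chrom", "pos", "id", "environments", "n_envs"])
    return out.sort_values(["chrom", "pos"]).reset_index(drop=True)


def ld_r2(geno, idx_a: int, idx_b: int) -> float:
    """Composite genotypic r^2 between two SNPs over pairwise-complete calls."""
    a = geno.calls[:, idx_a]
    b = geno.calls[:, idx_b]
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 3:
        return np.nan
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        return np.nan
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass
class QTL:
    qtl_id: str
    chrom: str
    start: int
    end: int
    members: list[str]
    peak_snp: str
    peak_p: float


def merge_snps_to_qtls(
    snps: pd.DataFrame,
    geno,
    max_gap: int = 100_000,
    min_r2: float = 0.35,
) -> pd.DataFrame:
    """Chain significant SNPs into QTLs: join adjacent SNPs on a chromosome
    when their distance is <= ``max_gap`` AND their r^2 exceeds ``min_r2``
    (single-linkage over position-sorted SNPs).  Every input SNP lands in
    exactly one QTL; the member with the smallest p is the peak.
    """
    required = {"chrom", "pos"}
    if not required <= set(snps.columns):
        raise ValueError(f"snps table needs columns {required}")
    snps = snps.sort_values(["chrom", "pos"]).reset_index(drop=True)
    idx = [geno.site_index(row["chrom"], row["pos"]) for _, row in snps.iterrows()]

    qtls: list[QTL] = []
    current: list[int] = []

    def close(current_rows: list[int]) -> None:
        if not current_rows:
            return
        sub = snps.iloc[current_rows]
        pvals = sub["p"].to_numpy(float) if "p" in sub.columns else np.full(len(sub), np.nan)
        peak = int(np.nanargmin(pvals)) if np.isfinite(pvals).any() else 0
        ids = [
            str(r["id"]) if "id" in sub.columns else f"{r['chrom']}_{r['pos']}"
            for _, r in sub.iterrows()
        ]
        qtls.append(
            QTL(
                qtl_id=f"QTL{len(qtls) + 1:03d}",
                chrom=str(sub.iloc[0]["chrom"]),
                start=int(sub["pos"].min()),
                end=int(sub["pos"].max()),
                members=ids,
                peak_snp=ids[peak],
                peak_p=float(pvals[peak]) if np.isfinite(pvals).any() else np.nan,
            )
        )

    for i in range(len(snps)):
        if not current:
            current = [i]
            continue
        prev = current[-1]
        same_chrom = snps.iloc[i]["chrom"] == snps.iloc[prev]["chrom"]
        near = abs(int(snps.iloc[i]["pos"]) - int(snps.iloc[prev]["pos"])) <= max_gap
        linked = same_chrom and near and ld_r2(geno, idx[prev], idx[i]) > min_r2
        if linked:
            current.append(i)
        else:
            close(current)
            current = [i]
    close(current)

    return pd.DataFrame(
        [
            {
                "qtl_id": q.qtl_id,
                "chrom": q.chrom,
                "start": q.start,
                "end": q.end,
                "n_snps": len(q.members),
                "members": ",".join(q.members),
                "peak_snp": q.peak_snp,
                "peak_p": q.peak_p,
            }
            for q in qtls
        ],
        columns=["qtl_id", "chrom", "start", "end", "n_snps", "members", "peak_snp", "peak_p"],
    )


def candidate_gene_windows(
    snps: pd.DataFrame,
    annotation: pd.DataFrame,
    flank: int = 100_000,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """+/- ``flank`` bp window around each SNP with the overlapping genes.

    Windows are clipped to [1, chromosome length]; a gene is included iff its
    interval overlaps the window by >= 1 bp (1-based inclusive coordinates).
    """
    known = set(annotation["chrom"]) | (set(chrom_lengths) if chrom_lengths else set())
    rows = []
    for _, snp in snps.iterrows():
        chrom, pos = snp["chrom"], int(snp["pos"])
        if known and chrom not in known:
            raise ValueError(f"unknown chromosome {chrom!r} for SNP {snp.get('id', pos)}")
        start = max(1, pos - flank)
        end = pos + flank
        if chrom_lengths and chrom in chrom_lengths:
            end = min(end, chrom_lengths[chrom])
        genes = annotation[
            (annotation["chrom"] == chrom)
            & (annotation["start"] <= end)
            & (annotation["end"] >= start)
        ]
        rows.append(
            {
                "snp_id": snp.get("id", f"{chrom}_{pos}"),
                "chrom": chrom,
                "pos": pos,
                "window_start": start,
                "window_end": end,
                "n_genes": len(genes),
                "genes": ",".join(genes["gene_id"]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["snp_id", "chrom", "pos", "window_start", "window_end", "n_genes", "genes"],
    )
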