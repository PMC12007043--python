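"""Synthetic genotype / phenotype / expression / annotation generator.

The generator emulates the statistical structure of a rapeseed
drought-tolerance diversity panel: ~200 accessions genotyped at genome-wide
SNPs with block-wise LD, a tolerant and a sensitive subpopulation that are
differentiated inside one planted sweep region, multi-environment
multi-treatment trait measurements with planted QTL effects and a polygenic
background, and an FPKM-style expression matrix with planted co-expression
modules correlated with treatment.

Linkage disequilibrium is induced block-wise: SNPs inside one ``ld_block_len``
window are copies of a small pool of founder haplotypes with per-allele
mutation noise, so nearby r² is high and decays at block boundaries.  This is
deliberately simpler than coalescent simulation — it is controllable,
desk-scale, and sufficient for r²-based QTL merging and regional haplotype
analysis.  Inside the planted sweep region the two subpopulations draw
founders from separate pools whose allele frequencies are separated so the
realized between-group differentiation approaches ``fst_target``.

All outputs are deterministic for a fixed seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (
    GENE_COLUMNS,
    PHENOTYPE_COLUMNS,
    ExpressionMatrix,
    GenomeSpec,
    GenotypeMatrix,
    ModuleSpecSim,
    QTLSpec,
    SweepSpec,
)

# Trait layout of the emulated panel: control-treatment mean, measurement
# stage, and whether drought stress raises or lowers the trait.  Chlorophyll
# readings rise under stress (leaves darken); everything else falls.
DEFAULT_TRAITS: dict[str, dict] = {
    "germination_rate": {"ck_mean": 90.0, "direction": "decrease"},
    "shoot_fresh_weight": {"ck_mean": 12.0, "direction": "decrease"},
    "root_fresh_weight": {"ck_mean": 3.0, "direction": "decrease"},
    "chlorophyll": {"ck_mean": 40.0, "direction": "increase"},
    "yield": {"ck_mean": 20.0, "direction": "decrease"},
}

DEFAULT_STRESS_EFFECT = {"CK": 1.0, "M": 0.6, "S": 0.35}


def _spread_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """n distinct sorted positions in [1, length]."""
    if n == 0:
        return np.empty(0, dtype=int)
    if n > length:
        raise ValueError(f"cannot place {n} distinct positions on {length} bp")
    pos: set[int] = set()
    while len(pos) < n:
        draw = rng.integers(1, length + 1, size=2 * (n - len(pos)))
        pos.update(int(x) for x in draw)
    chosen = rng.choice(np.fromiter(sorted(pos), dtype=int), size=n, replace=False)
    return np.sort(chosen)


def simulate_genotypes(
    genome: GenomeSpec,
    n_accessions: int,
    n_snps: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    ld_block_len: int = 50_000,
    subpop_split: tuple[int, int] | None = None,
    sweep: SweepSpec | None = None,
    missing_rate: float = 0.01,
    n_founders: int = 24,
    mutation_rate: float = 0.02,
    seed: int = 0,
) -> GenotypeMatrix:
    """Simulate a biallelic 0/1/2 panel with block-wise LD and a planted sweep.

    ``subpop_split = (n_tolerant, n_sensitive)`` labels the first accessions
    tolerant and the rest sensitive; inside the sweep region the two groups
    draw block founders from separate allele-frequency pools.
    """
    if n_accessions < 2:
        raise ValueError("need at least 2 accessions")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must lie in (0, 0.5]: got {maf_range}")
    if sweep is not None and not (
        genome.contains(sweep.chrom, sweep.start) and genome.contains(sweep.chrom, sweep.end)
    ):
        raise ValueError(
            f"sweep region {sweep.chrom}:{sweep.start}-{sweep.end} is outside the genome"
        )
    if subpop_split is None:
        subpop_split = (n_accessions // 2, n_accessions - n_accessions // 2)
    if sum(subpop_split) != n_accessions:
        raise ValueError("subpop_split must sum to n_accessions")

    rng = np.random.default_rng(seed)
    samples = [f"ACC{i + 1:04d}" for i in range(n_accessions)]
    subpop = pd.Series(
        ["tolerant"] * subpop_split[0] + ["sensitive"] * subpop_split[1], index=samples
    )
    group_b = np.arange(n_accessions) >= subpop_split[0]

    # Distribute SNPs across chromosomes proportionally to length.
    total = genome.total_length()
    alloc = [int(round(n_snps * length / total)) for _, length in genome.chromosomes]
    while sum(alloc) > n_snps:
        alloc[int(np.argmax(alloc))] -= 1
    while sum(alloc) < n_snps:
        alloc[int(np.argmin(alloc))] += 1

    bases = np.array(list("ACGT"))
    chrom_col, pos_col = [], []
    calls = np.empty((n_accessions, 0))
    blocks = []
    for (chrom, length), n_c in zip(genome.chromosomes, alloc):
        positions = _spread_positions(rng, length, n_c)
        chrom_col.extend([chrom] * n_c)
        pos_col.extend(positions.tolist())
        if n_c == 0:
            continue
        block_ids = positions // ld_block_len
        founder_mut = 0.05  # per-site divergence of founders from their core
        for bid in np.unique(block_ids):
            sel = block_ids == bid
            blocks.append((chrom, positions[sel]))
            m = int(sel.sum())
            # Two complementary core haplotypes per block; the alt core
            # segregates at a block frequency drawn from the MAF range, so
            # sites within a block co-inherit and nearby r^2 is high.
            q = rng.uniform(lo, hi)
            in_sweep = (
                sweep is not None
                and chrom == sweep.chrom
                and bool(((positions[sel] >= sweep.start) & (positions[sel] <= sweep.end)).any())
            )
            if in_sweep:
                # Split the core frequency between subpopulations so the
                # between-group differentiation approaches fst_target.  A
                # strongly differentiated region implies an intermediate
                # pooled frequency, so swept blocks segregate mid-range.
                q = rng.uniform(0.35, 0.65)
                d = 2.0 * np.sqrt(sweep.fst_target * q * (1.0 - q))
                q_a, q_b = q + d / 2.0, q - d / 2.0
                # Recenter rather than clip one side: the gap d sets the
                # differentiation, so preserve it when a bound binds.
                if q_a > 0.98:
                    q_a, q_b = 0.98, max(0.98 - d, 0.02)
                elif q_b < 0.02:
                    q_a, q_b = min(0.02 + d, 0.98), 0.02
                half = n_founders // 2
                n_alt_a = int(round(q_a * half))
                n_alt_b = int(round(q_b * (n_founders - half)))
                cores = np.concatenate(
                    [
                        np.repeat([1.0, 0.0], [n_alt_a, half - n_alt_a]),
                        np.repeat([1.0, 0.0], [n_alt_b, n_founders - half - n_alt_b]),
                    ]
                )
                # Accessions draw founders from their own pool; one of the
                # two haplotypes may cross pools (5% admixture), so a migrant
                # carries at most one foreign haplotype.
                own = np.ones((2, n_accessions), dtype=bool)
                own[1] = rng.random(n_accessions) < 0.95
                pool_a = rng.integers(0, half, size=(2, n_accessions))
                pool_b = rng.integers(half, n_founders, size=(2, n_accessions))
                idx = np.where(own ^ group_b[None, :], pool_a, pool_b)
            else:
                cores = (rng.random(n_founders) < q).astype(float)
                # Keep every block polymorphic at the founder level, with
                # enough minor-core copies to respect the MAF floor.
                min_cores = max(1, int(np.ceil(0.8 * lo * n_founders)))
                for _ in range(50):
                    if min_cores <= cores.sum() <= n_founders - min_cores:
                        break
                    cores = (rng.random(n_founders) < q).astype(float)
                idx = rng.integers(0, n_founders, size=(2, n_accessions))
            founders = np.repeat(cores[:, None], m, axis=1)
            if not in_sweep:
                # A swept region carries homogeneous haplotypes; elsewhere
                # majority-core founders diverge from their core at a low
                # per-site rate (minority cores stay intact so no site loses
                # its minor allele).
                majority = 1.0 if cores.mean() >= 0.5 else 0.0
                fflip = (rng.random(founders.shape) < founder_mut) & (cores[:, None] == majority)
                founders = np.where(fflip, 1.0 - founders, founders)
            h1 = founders[idx[0]]
            h2 = founders[idx[1]]
            if mutation_rate > 0:
                flip1 = rng.random(h1.shape) < mutation_rate
                flip2 = rng.random(h2.shape) < mutation_rate
                h1 = np.where(flip1, 1.0 - h1, h1)
                h2 = np.where(flip2, 1.0 - h2, h2)
            calls = np.hstack([calls, h1 + h2])

    sites = pd.DataFrame({"chrom": chrom_col, "pos": pos_col})
    if len(sites):
        ref = bases[rng.integers(0, 4, size=len(sites))]
        shift = rng.integers(1, 4, size=len(sites))
        alt = bases[(np.searchsorted(bases, ref) + shift) % 4]
    else:
        ref = np.empty(0, dtype=object)
        alt = np.empty(0, dtype=object)
    sites["id"] = [f"{c}_{p}" for c, p in zip(sites.get("chrom", []), sites.get("pos", []))]
    sites["ref"] = ref
    sites["alt"] = alt
    sites = sites.reindex(columns=["chrom", "pos", "id", "ref", "alt"])

    order = np.lexsort((sites["pos"].values, sites["chrom"].values)) if len(sites) else np.empty(0, int)
    sites = sites.iloc[order].reset_index(drop=True)
    calls = calls[:, order] if calls.size else np.empty((n_accessions, 0))

    if missing_rate > 0 and calls.size:
        mask = rng.random(calls.shape) < missing_rate
        calls[mask] = np.nan

    return GenotypeMatrix(samples=samples, sites=sites, calls=calls, subpop=subpop)


def simulate_phenotypes(
    geno: GenotypeMatrix,
    qtls: list[QTLSpec] | None = None,
    heritability: float = 0.5,
    treatments: tuple[str, ...] = ("CK", "M", "S"),
    environments: tuple[str, ...] = ("E1", "E2", "E3"),
    replicates: int = 3,
    traits: dict[str, dict] | None = None,
    stress_effect: dict[str, float] | None = None,
    cv: float = 0.25,
    env_sd: float = 0.05,
    group_stress_effect: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the long-format trait table the scoring pipeline consumes.

    Each measurement is ``mean(trait, treatment) * env * (1 + cv*(g + e))``
    where the standardized deviation ``g + e`` partitions into planted-QTL,
    polygenic and residual parts honoring ``heritability``.  Under stress
    treatments the tolerant subpopulation's stress-responsive traits shift up
    by ``group_stress_effect`` and the sensitive subpopulation's down, so the
    panel contains genuinely differentiated material.
    """
    if not 0.0 <= heritability < 1.0:
        raise ValueError("heritability must be in [0, 1)")
    if not treatments or not environments or replicates < 1:
        raise ValueError("design must be non-empty")
    qtls = qtls or []
    traits = traits or DEFAULT_TRAITS
    stress_effect = stress_effect or DEFAULT_STRESS_EFFECT
    for q in qtls:
        geno.site_index(q.chrom, q.pos)  # raises KeyError naming the locus

    rng = np.random.default_rng(seed)
    n = geno.n_samples

    def standardized_dosage(j: int) -> np.ndarray:
        g = geno.calls[:, j].copy()
        g[np.isnan(g)] = np.nanmean(g)
        sd = g.std()
        return (g - g.mean()) / sd if sd > 0 else np.zeros(n)

    # Polygenic value per trait: genome-wide random-weight combination so the
    # GWAS kinship correction has real structure to absorb.
    poly: dict[str, np.ndarray] = {}
    n_poly = min(geno.n_sites, 2000)
    poly_idx = (
        rng.choice(geno.n_sites, size=n_poly, replace=False) if n_poly else np.empty(0, int)
    )
    Z = (
        np.column_stack([standardized_dosage(j) for j in poly_idx])
        if n_poly
        else np.zeros((n, 0))
    )
    for trait in traits:
        if n_poly:
            u = Z @ rng.normal(size=n_poly)
            sd = u.std()
            poly[trait] = u / sd if sd > 0 else np.zeros(n)
        else:
            poly[trait] = np.zeros(n)

    qtl_z = {(q.chrom, q.pos): standardized_dosage(geno.site_index(q.chrom, q.pos)) for q in qtls}

    group_shift = np.zeros(n)
    if geno.subpop is not None:
        group_shift = np.where(np.asarray(geno.subpop) == "tolerant", 1.0, -1.0)

    env_mult = {
        (e, t): 1.0 + rng.normal(0.0, env_sd) for e in environments for t in treatments
    }

    rows = []
    for trait, cfg in traits.items():
        for treatment in treatments:
            se = stress_effect.get(treatment, 1.0)
            if cfg.get("direction", "decrease") == "increase":
                mult = 1.0 + 0.5 * (1.0 - se)
            else:
                mult = se
            base = cfg["ck_mean"] * mult

            # Variance partition of the standardized deviation.
            active = [
                q
                for q in qtls
                if q.affected_trait == trait and treatment in q.affected_treatments
            ]
            total_qtl = sum(q.effect_size for q in active)
            scale = 1.0 if total_qtl <= heritability or total_qtl == 0 else heritability / total_qtl
            g_val = np.zeros(n)
            used = 0.0
            for q in active:
                var_q = q.effect_size * scale * (1.0 if heritability > 0 else 0.0)
                g_val += np.sqrt(var_q) * qtl_z[(q.chrom, q.pos)]
                used += var_q
            poly_var = max(heritability - used, 0.0)
            g_val += np.sqrt(poly_var) * poly[trait]

            stress_shift = group_shift * group_stress_effect if treatment != "CK" else 0.0

            for env in environments:
                emult = env_mult[(env, treatment)]
                for rep in range(1, replicates + 1):
                    eps = rng.normal(size=n)
                    dev = g_val + np.sqrt(1.0 - heritability) * eps
                    values = base * emult * np.clip(1.0 + cv * dev + stress_shift, 0.0, None)
                    rows.append(
                        pd.DataFrame(
                            {
                                "accession": geno.samples,
                                "trait": trait,
                                "treatment": treatment,
                                "environment": env,
                                "replicate": rep,
                                "value": values,
                            }
                        )
                    )
    return pd.concat(rows, ignore_index=True)[PHENOTYPE_COLUMNS]


def simulate_expression(
    spec: ModuleSpecSim,
    sample_design: pd.DataFrame,
    seed: int = 0,
) -> ExpressionMatrix:
    """Simulate an FPKM-like matrix with planted co-expression modules.

    Each planted module is driven by one latent factor constructed to have
    the requested correlation with a binary treatment indicator from the
    design sheet (modules cycle through the non-control treatments);
    background genes are independent noise.  Values are linear in the factor
    so a noiseless module is perfectly internally correlated.
    """
    if sample_design.empty:
        raise ValueError("sample_design must be non-empty")
    rng = np.random.default_rng(seed)
    n_samples = len(sample_design)
    samples = list(sample_design["sample"])

    treatments = [t for t in pd.unique(sample_design["treatment"]) if t != "CK"]
    if not treatments:
        treatments = list(pd.unique(sample_design["treatment"]))

    amp = 0.3  # relative signal amplitude around each gene's baseline

    def standardize(x: np.ndarray) -> np.ndarray:
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    gene_rows = []
    gene_ids = []
    labels = []
    gene_counter = 0
    for m in range(spec.n_modules):
        target = treatments[m % len(treatments)]
        c = standardize((sample_design["treatment"] == target).to_numpy(float))
        g = standardize(rng.normal(size=n_samples))
        # Remove the component of g along c so the factor hits the target
        # correlation exactly in-sample.
        if c.any():
            g = g - (g @ c) / n_samples * c
            g = standardize(g)
        r = spec.trait_correlation
        factor = r * c + np.sqrt(max(1.0 - r * r, 0.0)) * g
        factor = standardize(factor) if factor.std() > 0 else factor
        for _ in range(spec.genes_per_module):
            gene_counter += 1
            mu = rng.uniform(5.0, 50.0)
            sign = rng.choice([-1.0, 1.0])
            noise = rng.normal(size=n_samples) * spec.noise_sd
            profile = mu * (1.0 + amp * (sign * factor + noise))
            gene_rows.append(np.clip(profile, 0.0, None))
            gene_ids.append(f"GENE{gene_counter:05d}")
            labels.append(f"planted_{m + 1}")
    for _ in range(spec.n_background):
        gene_counter += 1
        mu = rng.uniform(5.0, 50.0)
        profile = mu * (1.0 + amp * rng.normal(size=n_samples))
        gene_rows.append(np.clip(profile, 0.0, None))
        gene_ids.append(f"GENE{gene_counter:05d}")
        labels.append("background")

    values = pd.DataFrame(np.array(gene_rows), index=gene_ids, columns=samples)
    return ExpressionMatrix(
        values=values,
        design=sample_design.reset_index(drop=True),
        planted_modules=pd.Series(labels, index=gene_ids, name="planted_module"),
    )


def default_sample_design(
    treatments: tuple[str, ...] = ("CK", "M", "S"),
    tissues: tuple[str, ...] = ("root", "leaf"),
    groups: tuple[str, ...] = ("tolerant", "sensitive"),
    replicates: int = 2,
) -> pd.DataFrame:
    """Design sheet mirroring a tolerant/sensitive RNA-seq contrast layout."""
    rows = []
    i = 0
    for tissue in tissues:
        for treatment in treatments:
            for group in groups:
                for rep in range(1, replicates + 1):
                    i += 1
                    rows.append(
                        {
                            "sample": f"S{i:03d}",
                            "tissue": tissue,
                            "treatment": treatment,
                            "group": group,
                            "replicate": rep,
                        }
                    )
    return pd.DataFrame(rows)


def simulate_annotation(
    genome: GenomeSpec,
    n_genes: int,
    length_range: tuple[int, int] = (500, 5_000),
    seed: int = 0,
) -> pd.DataFrame:
    """Place non-overlapping gene models (1-based inclusive) on the genome.

    Each chromosome's allocation is proportional to its length; genes are
    placed one per equal-width slot at a random offset, which guarantees
    non-overlap by construction.
    """
    lo, hi = length_range
    if lo <= 0 or hi < lo:
        raise ValueError(f"length_range must be a positive interval: got {length_range}")
    if n_genes < 0:
        raise ValueError("n_genes must be non-negative")
    rng = np.random.default_rng(seed)
    if n_genes == 0:
        return pd.DataFrame(columns=GENE_COLUMNS)

    total = genome.total_length()
    alloc = [int(round(n_genes * length / total)) for _, length in genome.chromosomes]
    while sum(alloc) > n_genes:
        alloc[int(np.argmax(alloc))] -= 1
    while sum(alloc) < n_genes:
        alloc[int(np.argmin(alloc))] += 1

    rows = []
    gid = 0
    for (chrom, length), n_c in zip(genome.chromosomes, alloc):
        if n_c == 0:
            continue
        slot = length // n_c
        if slot <= lo:
            raise ValueError(
                f"chromosome {chrom} ({length} bp) cannot hold {n_c} "
                f"non-overlapping genes of at least {lo} bp"
            )
        for k in range(n_c):
            gid += 1
            gene_len = int(rng.integers(lo, min(hi, slot - 1) + 1))
            offset = int(rng.integers(0, slot - gene_len + 1))
            start = k * slot + 1 + offset
            end = start + gene_len - 1
            rows.append(
                {
                    "gene_id": f"GM{gid:05d}",
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "strand": "+" if rng.random() < 0.5 else "-",
                }
            )
    return pd.DataFrame(rows, columns=GENE_COLUMNS)
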