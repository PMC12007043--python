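"""Regional LD (r2, EM D'), regional association, haplotype grouping."""

import itertools

import numpy as np
import pandas as pd
import pytest

from droughtgwas import haplotype, simulate
from droughtgwas.datatypes import SweepSpec
from droughtgwas.gwas import ld_r2

from conftest import make_genotypes


def dprime_grid_oracle(g1, g2, resolution=4001):
    """Exhaustive-likelihood oracle for D'.

    With dosages fully observed, the ML haplotype frequencies keep the
    observed allele frequencies as margins, leaving a single free parameter
    p_AB; the oracle scans it on a fine grid (with one local refinement) and
    returns D' at the maximum-likelihood point.
    """
    ok = ~np.isnan(g1) & ~np.isnan(g2)
    g1, g2 = g1[ok].astype(int), g2[ok].astype(int)
    counts = np.zeros((3, 3))
    for a, b in zip(g1, g2):
        counts[a, b] += 1
    pA = 1.0 - g1.mean() / 2.0
    pB = 1.0 - g2.mean() / 2.0
    lo = max(0.0, pA + pB - 1.0)
    hi = min(pA, pB)

    def ll(pab):
        f = np.array([pab, pA - pab, pB - pab, 1.0 - pA - pB + pab])
        if (f < -1e-12).any():
            return -np.inf
        return haplotype.genotype_loglik(counts, np.clip(f, 0.0, 1.0))

    grid = np.linspace(lo, hi, resolution)
    vals = [ll(x) for x in grid]
    best = int(np.argmax(vals))
    span = (hi - lo) / (resolution - 1)
    fine = np.linspace(max(lo, grid[best] - span), min(hi, grid[best] + span), 2001)
    fvals = [ll(x) for x in fine]
    pab = fine[int(np.argmax(fvals))]
    f = np.array([pab, pA - pab, pB - pab, 1.0 - pA - pB + pab])
    return haplotype.d_prime(f)


class TestRegionalLD:
    def test_duplicate_column_r2_dprime_one(self):
        rng = np.random.default_rng(1)
        col = rng.integers(0, 3, size=40).astype(float)
        geno = make_genotypes(np.column_stack([col, col]), positions=[100, 200])
        ld = haplotype.regional_ld(geno, "A01", 1, 1000)
        assert ld.r2.iloc[0, 1] == pytest.approx(1.0)
        assert abs(ld.dprime.iloc[0, 1]) == pytest.approx(1.0, abs=1e-6)

    def test_independent_snps_r2_zero(self):
        a = np.array([0, 0, 1, 1, 2, 2] * 4, dtype=float)
        b = np.array([0, 1, 2, 0, 1, 2] * 4, dtype=float)
        b = b[np.argsort(np.tile([0, 1, 2], 8), kind="stable")]  # decorrelate
        geno = make_genotypes(np.column_stack([a, b - b.mean() * 0]), positions=[100, 200])
        r = np.corrcoef(a, geno.calls[:, 1])[0, 1]
        ld = haplotype.regional_ld(geno, "A01", 1, 1000)
        assert ld.r2.iloc[0, 1] == pytest.approx(r * r, abs=1e-12)

    def test_r2_consistent_with_gwas_ld(self, small_panel):
        geno, sweep = small_panel
        ld = haplotype.regional_ld(geno, sweep.chrom, sweep.start, sweep.end)
        sub = geno.subset_sites(geno.region_mask(sweep.chrom, sweep.start, sweep.end))
        poly = sub.maf() > 0
        sub = sub.subset_sites(poly)
        for i, j in itertools.combinations(range(min(sub.n_sites, 5)), 2):
            assert ld.r2.iloc[i, j] == pytest.approx(ld_r2(sub, i, j), abs=1e-12)

    def test_em_dprime_matches_grid_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            # correlated pair via shared haplotypes
            h = rng.integers(0, 2, size=(2, 200)).astype(float)
            flip = rng.random((2, 200)) < 0.2
            g1 = h.sum(axis=0)
            g2 = np.where(flip, 1 - h, h).sum(axis=0)
            em = haplotype.em_haplotype_freqs(g1, g2)
            dp_em = haplotype.d_prime(em)
            dp_oracle = dprime_grid_oracle(g1, g2)
            assert dp_em == pytest.approx(dp_oracle, abs=1e-4)

    def test_em_loglik_nondecreasing(self):
        rng = np.random.default_rng(6)
        g1 = rng.integers(0, 3, size=100).astype(float)
        g2 = np.clip(g1 + rng.integers(-1, 2, size=100), 0, 2).astype(float)
        _, trace = haplotype.em_haplotype_freqs(g1, g2, return_trace=True)
        assert len(trace) >= 1
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_too_few_snps_rejected(self):
        col = np.array([0.0, 1.0, 2.0])
        geno = make_genotypes(col[:, None], positions=[100])
        with pytest.raises(ValueError, match="fewer than 2"):
            haplotype.regional_ld(geno, "A01", 1, 1000)


class TestRegionalAssociation:
    def test_null_flag_rate_consistent_with_threshold(self):
        """125 independent SNPs x 5 seeds at -log10(p) >= 2.5: ~2 flags expected."""
        total = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            calls = rng.binomial(2, 0.3, size=(193, 125)).astype(float)
            geno = make_genotypes(calls, positions=np.arange(1, 126) * 100)
            y = pd.Series(rng.normal(size=193), index=geno.samples)
            out = haplotype.regional_association(geno, "A01", 1, 20_000, y)
            total += int(out["flagged"].sum())
        assert total <= 7  # Poisson(~2) upper tail

    def test_planted_causal_snp_flagged(self):
        rng = np.random.default_rng(7)
        calls = rng.binomial(2, 0.4, size=(193, 20)).astype(float)
        geno = make_genotypes(calls, positions=np.arange(1, 21) * 100)
        g = calls[:, 10]
        y = pd.Series(0.3 * (g - g.mean()) / g.std() + rng.normal(scale=np.sqrt(1 - 0.09), size=193),
                      index=geno.samples)
        out = haplotype.regional_association(geno, "A01", 1, 20_000, y)
        assert bool(out["flagged"].iloc[10])

    def test_zero_threshold_flags_everything_testable(self):
        rng = np.random.default_rng(8)
        calls = rng.binomial(2, 0.4, size=(50, 10)).astype(float)
        geno = make_genotypes(calls, positions=np.arange(1, 11) * 100)
        y = pd.Series(rng.normal(size=50), index=geno.samples)
        out = haplotype.regional_association(geno, "A01", 1, 20_000, y, threshold_neglog10p=0.0)
        assert out["flagged"].all()


class TestHaplotypes:
    def test_uniform_region_single_haplotype(self):
        calls = np.tile([0.0, 2.0, 1.0], (20, 1))
        geno = make_genotypes(calls, positions=[100, 200, 300])
        haps = haplotype.assign_haplotypes(geno, "A01", 1, 1000)
        assert len(haps) == 1
        assert haps.iloc[0]["n_carriers"] == 20
        assert haps.iloc[0]["genotype_string"] == "0/0-1/1-0/1"

    def test_single_divergent_accession_forms_own_haplotype(self):
        calls = np.tile([0.0, 0.0], (10, 1))
        calls[3, 1] = 1.0
        geno = make_genotypes(calls, positions=[100, 200])
        haps = haplotype.assign_haplotypes(geno, "A01", 1, 1000)
        assert len(haps) == 2
        assert haps.iloc[1]["n_carriers"] == 1

    def test_permutation_stable_numbering(self):
        rng = np.random.default_rng(9)
        calls = rng.integers(0, 3, size=(30, 4)).astype(float)
        geno = make_genotypes(calls, positions=[10, 20, 30, 40])
        haps = haplotype.assign_haplotypes(geno, "A01", 1, 100)
        perm = rng.permutation(30)
        geno_p = make_genotypes(calls[perm], samples=[geno.samples[i] for i in perm],
                                positions=[10, 20, 30, 40])
        haps_p = haplotype.assign_haplotypes(geno_p, "A01", 1, 100)
        assert list(haps["genotype_string"]) == list(haps_p["genotype_string"])
        carriers = haps["carriers"].apply(lambda s: frozenset(s.split(",")))
        carriers_p = haps_p["carriers"].apply(lambda s: frozenset(s.split(",")))
        assert list(carriers) == list(carriers_p)

    def test_partition_property(self, small_panel):
        geno, sweep = small_panel
        haps = haplotype.assign_haplotypes(geno, sweep.chrom, sweep.start, sweep.end)
        included = geno.n_samples - len(haps.attrs["excluded"])
        assert haps["n_carriers"].sum() == included

    def test_missing_heavy_accessions_excluded(self):
        calls = np.zeros((5, 4))
        calls[0, :3] = np.nan
        geno = make_genotypes(calls, positions=[10, 20, 30, 40])
        with pytest.warns(UserWarning, match="excluded"):
            haps = haplotype.assign_haplotypes(geno, "A01", 1, 100, max_missing_frac=0.5)
        assert haps["n_carriers"].sum() == 4


class TestHaplotypeClassDistribution:
    def _haps(self):
        return pd.DataFrame(
            {
                "haplotype": ["Hap1", "Hap2"],
                "genotype_string": ["0/0", "1/1"],
                "n_carriers": [3, 4],
                "carriers": ["a1,a2,a3", "b1,b2,a4,a5"],
            }
        )

    def test_exclusive_flag(self):
        classes = pd.Series(
            {"a1": "tolerant", "a2": "tolerant", "a3": "tolerant",
             "b1": "sensitive", "b2": "sensitive", "a4": "tolerant", "a5": "medium"}
        )
        out = haplotype.haplotype_class_distribution(self._haps(), classes)
        assert out.iloc[0]["exclusive_to"] == "tolerant"
        assert out.iloc[1]["exclusive_to"] == ""
        assert out.iloc[1]["sensitive"] == 2

    def test_unclassified_counted_with_warning(self):
        classes = pd.Series({"a1": "tolerant", "a2": "tolerant", "a3": "tolerant",
                             "b1": "sensitive", "b2": "sensitive", "a4": "tolerant"})
        with pytest.warns(UserWarning, match="lack"):
            out = haplotype.haplotype_class_distribution(self._haps(), classes)
        assert out.iloc[1]["unclassified"] == 1

    def test_planted_tolerant_exclusive_haplotype_flagged(self, small_genome):
        """A strongly swept region yields a tolerant-only major haplotype."""
        sweep = SweepSpec("B01", 1_000_000, 1_030_000, 1.0)
        geno = simulate.simulate_genotypes(
            small_genome, 100, 1000, sweep=sweep, seed=5,
            missing_rate=0.0, mutation_rate=0.0,
        )
        haps = haplotype.assign_haplotypes(geno, "B01", sweep.start, sweep.end)
        classes = geno.subpop
        out = haplotype.haplotype_class_distribution(haps, classes)
        major = out.head(4)
        assert (major["exclusive_to"] == "tolerant").any()
        # and the two biggest haplotypes are dominated by opposite subgroups
        # (a few carriers cross over via the simulated 5% migration)
        top2 = out.head(2)
        purities = {
            row["haplotype"]: max(row["pct_tolerant"], row["pct_sensitive"])
            for _, row in top2.iterrows()
        }
        assert all(p >= 90.0 for p in purities.values())
        dominant = {
            ("tolerant" if row["pct_tolerant"] > row["pct_sensitive"] else "sensitive")
            for _, row in top2.iterrows()
        }
        assert dominant == {"tolerant", "sensitive"}
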