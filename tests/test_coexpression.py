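"""TOM construction, module detection, eigengenes, module-trait tests, DE."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from droughtgwas import coexpression, simulate
from droughtgwas.datatypes import ExpressionMatrix, ModuleSpecSim


def _expr(values, sample_prefix="S"):
    values = np.asarray(values, float)
    genes = [f"g{i}" for i in range(values.shape[0])]
    samples = [f"{sample_prefix}{j}" for j in range(values.shape[1])]
    design = pd.DataFrame(
        {"sample": samples, "tissue": "root", "treatment": "CK", "group": "a"}
    )
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples), design=design
    )


def tom_oracle(X, power):
    """Literal loop transcription of the unsigned TOM formula."""
    n = X.shape[0]
    cor = np.corrcoef(X)
    a = np.abs(cor) ** power
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            tom[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


class TestFilter:
    def test_identity_at_zero_threshold(self):
        expr = _expr(np.ones((4, 5)))
        out = coexpression.filter_expression(expr, min_fpkm=0.0, min_samples=0)
        assert out.values.shape == (4, 5)

    def test_low_sample_support_removed(self):
        vals = np.zeros((2, 5))
        vals[0] = [5, 5, 5, 0, 0]
        vals[1] = [5, 5, 0, 0, 0]
        out = coexpression.filter_expression(_expr(vals), min_fpkm=1.0, min_samples=3)
        assert list(out.values.index) == ["g0"]

    def test_all_zero_genes_removed_at_defaults(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(2, 10, size=(50, 6))
        vals[::10] = 0.0
        out = coexpression.filter_expression(_expr(vals))
        assert len(out.values) == 45

    def test_everything_removed_aborts(self):
        with pytest.raises(ValueError, match="no genes"):
            coexpression.filter_expression(_expr(np.zeros((3, 4))))


class TestAdjacencyTom:
    def test_perfect_pair_with_independent_third(self):
        t = np.linspace(0, 1, 8)
        orth = np.array([1, -1, 1, -1, 1, -1, 1, -1.0])
        orth = orth - orth.mean()
        base = t - t.mean()
        orth = orth - (orth @ base) / (base @ base) * base  # exact orthogonality
        X = np.vstack([t, 2 * t + 5, orth + 10])
        tom = coexpression.adjacency_tom(pd.DataFrame(X, index=list("abc")), power=9)
        assert tom.loc["a", "b"] == pytest.approx(1.0, abs=1e-10)

    def test_matches_loop_oracle_random(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            X = rng.normal(size=(20, 10))
            tom = coexpression.adjacency_tom(pd.DataFrame(X), power=9).to_numpy()
            oracle = tom_oracle(X, 9)
            np.testing.assert_allclose(tom, oracle, atol=1e-12)

    def test_hand_set_correlations_beta_two(self):
        """3 genes; TOM entries recomputed from the formula by hand."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(3, 50))
        tom = coexpression.adjacency_tom(pd.DataFrame(X), power=2).to_numpy()
        oracle = tom_oracle(X, 2)
        np.testing.assert_allclose(tom, oracle, atol=1e-12)

    def test_tom_bounds_and_symmetry(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(15, 12))
        tom = coexpression.adjacency_tom(pd.DataFrame(X), power=6).to_numpy()
        assert (tom >= 0).all() and (tom <= 1).all()
        assert np.allclose(tom, tom.T)
        assert np.allclose(np.diag(tom), 1.0)

    def test_higher_power_sparsifies(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 8))
        cor = np.abs(np.corrcoef(X))
        assert (cor**9).mean() <= (cor**6).mean()

    def test_constant_gene_rejected(self):
        X = np.vstack([np.ones(6), np.arange(6.0)])
        with pytest.raises(ValueError, match="constant"):
            coexpression.adjacency_tom(pd.DataFrame(X, index=["flat", "ok"]))


class TestDetectModules:
    def test_two_noiseless_blocks(self):
        rng = np.random.default_rng(6)
        f1, f2 = rng.normal(size=(2, 12))
        X = np.vstack([
            np.outer(rng.uniform(0.5, 2, 60), f1),
            np.outer(rng.uniform(0.5, 2, 60), f2),
        ]) + rng.normal(scale=1e-6, size=(120, 12))
        vals = pd.DataFrame(X, index=[f"g{i}" for i in range(120)])
        tom = coexpression.adjacency_tom(vals, power=9)
        ms = coexpression.detect_modules(tom, vals, min_module_size=50)
        assert len(ms.sizes) == 2
        lab = ms.labels
        assert lab.iloc[:60].nunique() == 1 and lab.iloc[60:].nunique() == 1
        assert lab.iloc[0] != lab.iloc[60]

    def test_planted_modules_recovered_ari(self):
        spec = ModuleSpecSim(n_modules=3, genes_per_module=100, trait_correlation=0.8,
                             noise_sd=0.5, n_background=200)
        expr = simulate.simulate_expression(spec, simulate.default_sample_design(), seed=3)
        filt = coexpression.filter_expression(expr)
        tom = coexpression.adjacency_tom(filt.values, power=9)
        ms = coexpression.detect_modules(tom, filt.values, min_module_size=50)
        planted = filt.planted_modules[filt.planted_modules != "background"]
        ari = adjusted_rand_score(planted, ms.labels[planted.index])
        assert ari >= 0.8

    def test_too_few_genes_all_grey(self):
        rng = np.random.default_rng(7)
        vals = pd.DataFrame(rng.normal(size=(10, 6)))
        tom = coexpression.adjacency_tom(vals, power=2)
        with pytest.warns(UserWarning, match="unassigned"):
            ms = coexpression.detect_modules(tom, vals, min_module_size=50)
        assert (ms.labels == "grey").all()

    def test_gene_order_permutation_same_partition(self):
        spec = ModuleSpecSim(n_modules=2, genes_per_module=60, trait_correlation=0.7,
                             noise_sd=0.3, n_background=30)
        expr = simulate.simulate_expression(spec, simulate.default_sample_design(), seed=8)
        vals = expr.values
        tom = coexpression.adjacency_tom(vals, power=9)
        ms = coexpression.detect_modules(tom, vals, min_module_size=50)
        rng = np.random.default_rng(9)
        perm = rng.permutation(len(vals))
        vals_p = vals.iloc[perm]
        tom_p = coexpression.adjacency_tom(vals_p, power=9)
        ms_p = coexpression.detect_modules(tom_p, vals_p, min_module_size=50)
        ari = adjusted_rand_score(ms.labels.sort_index(), ms_p.labels.sort_index())
        assert ari == pytest.approx(1.0)


class TestEigengenes:
    def test_single_gene_module(self):
        rng = np.random.default_rng(10)
        vals = pd.DataFrame(rng.normal(size=(1, 8)), index=["g0"])
        labels = pd.Series(["blue"], index=["g0"])
        me = coexpression.module_eigengenes(vals, labels)
        x = vals.iloc[0].to_numpy()
        z = (x - x.mean()) / x.std()
        np.testing.assert_allclose(me.loc["blue"], z, atol=1e-10)

    def test_identical_genes_module(self):
        profile = np.arange(8.0)
        vals = pd.DataFrame(np.tile(profile, (5, 1)), index=[f"g{i}" for i in range(5)])
        labels = pd.Series("blue", index=vals.index)
        me = coexpression.module_eigengenes(vals, labels)
        z = (profile - profile.mean()) / profile.std()
        np.testing.assert_allclose(me.loc["blue"], z, atol=1e-10)

    def test_pc1_variance_matches_eigen_oracle(self):
        rng = np.random.default_rng(11)
        vals = pd.DataFrame(rng.normal(size=(50, 10)))
        labels = pd.Series("blue", index=vals.index)
        me = coexpression.module_eigengenes(vals, labels)
        Z = ((vals.T - vals.mean(axis=1)) / vals.std(axis=1)).T.to_numpy()
        _, s, Vt = np.linalg.svd(Z, full_matrices=False)
        explained = s[0] ** 2 / (s**2).sum()
        proj = Z @ (me.loc["blue"] / np.linalg.norm(me.loc["blue"]))
        achieved = (proj**2).sum() / (Z**2).sum()
        assert achieved == pytest.approx(explained, abs=1e-8)
        # Rayleigh property: no other direction explains more
        rng2 = np.random.default_rng(12)
        for _ in range(20):
            v = rng2.normal(size=10)
            v /= np.linalg.norm(v)
            assert ((Z @ v) ** 2).sum() <= (proj**2).sum() + 1e-8


class TestModuleTrait:
    def test_self_covariate_perfect(self):
        rng = np.random.default_rng(13)
        e = rng.normal(size=12)
        me = pd.DataFrame([e / e.std()], index=["blue"])
        traits = pd.DataFrame({"cov": me.loc["blue"].to_numpy()})
        out = coexpression.module_trait_correlation(me, traits)
        assert out["r"].iloc[0] == pytest.approx(1.0)
        assert out["stars"].iloc[0] == "***"

    def test_orthogonal_covariate_zero(self):
        e = np.array([1.0, -1.0] * 6)
        cov = np.array([1.0, 1.0, -1.0, -1.0] * 3)
        cov = cov - (cov @ e) / (e @ e) * e
        me = pd.DataFrame([e], index=["blue"])
        out = coexpression.module_trait_correlation(me, pd.DataFrame({"cov": cov}))
        assert out["r"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_p_matches_t_cdf_oracle(self):
        """n=12, r=0.6: p equals the closed-form t transform."""
        n, r = 12, 0.6
        rng = np.random.default_rng(14)
        x = rng.normal(size=n)
        x = (x - x.mean()) / x.std()
        noise = rng.normal(size=n)
        noise -= noise.mean()
        noise -= (noise @ x) / (x @ x) * x
        noise /= noise.std()
        e = r * x + np.sqrt(1 - r**2) * noise
        me = pd.DataFrame([e], index=["blue"])
        out = coexpression.module_trait_correlation(me, pd.DataFrame({"cov": x}))
        t = r * np.sqrt((n - 2) / (1 - r**2))
        expected = 2 * stats.t.sf(abs(t), n - 2)
        assert out["r"].iloc[0] == pytest.approx(r, abs=1e-12)
        assert out["p"].iloc[0] == pytest.approx(expected, abs=1e-10)

    def test_zero_variance_covariate_skipped(self):
        me = pd.DataFrame([np.arange(6.0)], index=["blue"])
        with pytest.warns(UserWarning, match="zero variance"):
            out = coexpression.module_trait_correlation(me, pd.DataFrame({"flat": np.ones(6)}))
        assert out.empty


class TestDifferentialExpression:
    def test_identical_groups_no_calls(self):
        rng = np.random.default_rng(15)
        half = rng.uniform(1, 20, size=(30, 3))
        expr = _expr(np.hstack([half, half]))
        out = coexpression.differential_expression(
            expr, list(expr.values.columns[:3]), list(expr.values.columns[3:])
        )
        assert out["significant"].sum() == 0

    def test_planted_sixteen_fold_gene_flagged_up(self):
        rng = np.random.default_rng(16)
        vals = rng.uniform(4, 6, size=(20, 8))
        vals[0, :4] = 80.0 + rng.normal(scale=0.01, size=4)
        vals[0, 4:] = 5.0 + rng.normal(scale=0.01, size=4)
        expr = _expr(vals)
        cols = list(expr.values.columns)
        out = coexpression.differential_expression(expr, cols[:4], cols[4:])
        assert bool(out["significant"].iloc[0])
        assert out["direction"].iloc[0] == "up"
        assert out["log2fc"].iloc[0] > 2

    def test_null_bh_rate_within_nominal(self):
        rng = np.random.default_rng(9)
        vals = np.exp(rng.normal(2, 1, size=(2000, 8)))
        expr = _expr(vals)
        cols = list(expr.values.columns)
        out = coexpression.differential_expression(expr, cols[:4], cols[4:], min_log2fc=0.0)
        assert out["significant"].sum() <= 40
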