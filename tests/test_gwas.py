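import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from awmnet.gwas import (
    Grm,
    MlmaGwas,
    VarianceComponents,
    bonferroni_threshold,
    compute_grm,
    fit_null_model,
    run_gwas,
    wald_neglog10p,
)
from awmnet.simulate import GenotypeMatrix, TraitPanel, TrueArchitecture, \
    simulate_genotypes, simulate_phenotypes


def dense_gls_oracle(y, X, G, s2u, s2e):
    """Explicit-V-inverse GLS with intercept, one variant at a time."""
    n = len(y)
    V = s2u * G + s2e * np.eye(n)
    Vi = np.linalg.inv(V)
    out_b, out_se = [], []
    for j in range(X.shape[1]):
        A = np.column_stack([np.ones(n), X[:, j]])
        C = np.linalg.inv(A.T @ Vi @ A)
        beta = C @ A.T @ Vi @ y
        out_b.append(beta[1])
        out_se.append(np.sqrt(C[1, 1]))
    return np.array(out_b), np.array(out_se)


def toy_geno(dosages, chrom="1"):
    n, v = dosages.shape
    p = dosages.mean(axis=0) / 2
    return GenotypeMatrix(
        dosages=dosages.astype(float),
        variants=pd.DataFrame({
            "id": [f"v{j}" for j in range(v)],
            "chrom": [chrom] * v,
            "pos": np.arange(1, v + 1) * 1000,
            "ref": ["A"] * v,
            "alt": ["C"] * v,
            "maf": np.minimum(p, 1 - p),
        }),
        individuals=[f"s{i}" for i in range(n)],
    )


class TestGrm:
    def test_two_individual_hand_example(self):
        g = toy_geno(np.array([[0.0], [2.0]]))
        grm = compute_grm(g)
        assert np.allclose(grm.matrix, [[2, -2], [-2, 2]])
        assert grm.n_variants_used == 1

    def test_duplicate_individuals_share_rows(self, small_geno):
        d = small_geno.dosages[:50].copy()
        d[1] = d[0]
        grm = compute_grm(toy_geno(d)).matrix
        assert np.allclose(grm[0], grm[1])

    def test_mean_diagonal_near_one(self):
        g = simulate_genotypes(50, 1000, ld_block_len=1, seed=9)
        grm = compute_grm(g)
        assert 0.8 <= np.mean(np.diag(grm.matrix)) <= 1.2

    def test_monomorphic_only_raises(self):
        g = toy_geno(np.full((5, 3), 2.0))
        with pytest.raises(ValueError, match="monomorphic"):
            compute_grm(g)

    def test_monomorphic_columns_skipped(self):
        d = np.array([[0.0, 2.0], [2.0, 2.0]])
        grm = compute_grm(toy_geno(d))
        assert grm.n_variants_used == 1
        assert np.allclose(grm.matrix, [[2, -2], [-2, 2]])


class TestReml:
    def test_null_trait_gives_low_h2(self):
        hits = 0
        for seed in range(10):
            g = simulate_genotypes(500, 400, seed=300 + seed)
            rng = np.random.default_rng(400 + seed)
            vc = fit_null_model(rng.standard_normal(500), compute_grm(g))
            hits += vc.h2 <= 0.1
        assert hits >= 8

    def test_constant_phenotype_raises(self, small_geno):
        grm = compute_grm(small_geno)
        with pytest.raises(ValueError, match="zero variance"):
            fit_null_model(np.ones(small_geno.n_individuals), grm)

    def test_nonfinite_phenotype_raises(self, small_geno):
        grm = compute_grm(small_geno)
        y = np.zeros(small_geno.n_individuals)
        y[0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_null_model(y, grm)

    def test_variance_components_positive_and_converged(self, small_geno, null_panel):
        vc = fit_null_model(null_panel.values[:, 0], compute_grm(small_geno))
        assert vc.sigma2_u >= 0 and vc.sigma2_e > 0 and vc.converged


class TestMlmaScan:
    @pytest.mark.parametrize("h2_true", [0.0, 0.5])
    def test_matches_dense_gls_oracle(self, h2_true):
        g = simulate_genotypes(50, 20, ld_block_len=5, seed=21)
        arch = TrueArchitecture(np.zeros((20, 1)), h2_true, np.eye(1), seed=22)
        panel = simulate_phenotypes(g, arch)
        res = MlmaGwas(panel, g).fit()
        vc = res.variance_components["trait00"]
        b0, se0 = dense_gls_oracle(
            panel.values[:, 0], g.dosages, compute_grm(g).matrix, vc.sigma2_u, vc.sigma2_e
        )
        assert np.allclose(res.effects["trait00"], b0, rtol=1e-8)
        assert np.allclose(res.se["trait00"], se0, rtol=1e-8)

    def test_allele_flip_negates_effect_only(self):
        g = simulate_genotypes(100, 10, seed=31)
        arch = TrueArchitecture(np.zeros((10, 1)), 0.0, np.eye(1), seed=32)
        panel = simulate_phenotypes(g, arch)
        res = MlmaGwas(panel, g).fit()
        flipped = toy_geno(2.0 - g.dosages)
        res2 = MlmaGwas(TraitPanel(panel.values, panel.traits, panel.key_trait,
                                   list(flipped.individuals)), flipped,
                        grm=compute_grm(g)).fit()
        assert np.allclose(res2.effects.to_numpy(), -res.effects.to_numpy())
        assert np.allclose(res2.se.to_numpy(), res.se.to_numpy())
        assert np.allclose(res2.neglog10p.to_numpy(), res.neglog10p.to_numpy())

    def test_degenerate_variant_flagged(self):
        d = np.column_stack([np.full(30, 1.0), np.random.default_rng(3).integers(0, 3, 30)])
        g = toy_geno(d)
        rng = np.random.default_rng(4)
        panel = TraitPanel(rng.standard_normal((30, 1)), ["t"], "t", list(g.individuals))
        grm = Grm(np.eye(30), 1)
        res = MlmaGwas(panel, g, grm=grm).fit()
        assert res.degenerate.iloc[0, 0]
        assert res.effects.iloc[0, 0] == 0.0
        assert res.neglog10p.iloc[0, 0] == 0.0

    def test_type_one_error_calibrated_under_null(self, small_geno, null_panel):
        """Fraction of p < 0.05 is 0.05 +/- 0.01 over 10,000 null tests."""
        g = simulate_genotypes(500, 2000, seed=77)
        arch = TrueArchitecture(np.zeros((2000, 5)), 0.0, np.eye(5), seed=78)
        panel = simulate_phenotypes(g, arch)
        res = MlmaGwas(panel, g).fit()
        frac = float((res.pvalues.to_numpy() < 0.05).mean())
        assert abs(frac - 0.05) <= 0.01

    def test_null_pvalues_uniform(self):
        g = simulate_genotypes(300, 2000, seed=91)
        arch = TrueArchitecture(np.zeros((2000, 1)), 0.0, np.eye(1), seed=92)
        panel = simulate_phenotypes(g, arch)
        res = MlmaGwas(panel, g).fit()
        from scipy.stats import kstest

        assert kstest(res.pvalues.to_numpy().ravel(), "uniform").pvalue > 0.01

    def test_planted_effect_detected_at_bonferroni(self):
        """5%-variance causal variant is genome-wide significant in >= 9/10 seeds."""
        _, nlp_thr = bonferroni_threshold(2000)
        hits = 0
        for seed in range(10):
            g = simulate_genotypes(2000, 2000, ld_block_len=25, seed=500 + seed)
            beta = np.zeros((2000, 1))
            p = g.alt_freq()[1000]
            beta[1000, 0] = np.sqrt((0.05 / 0.95) / (2 * p * (1 - p)))
            arch = TrueArchitecture(beta, 0.2, np.eye(1), seed=600 + seed)
            panel = simulate_phenotypes(g, arch)
            res = MlmaGwas(panel, g).fit()
            hits += res.neglog10p.iloc[1000, 0] > nlp_thr
        assert hits >= 9

    def test_run_gwas_reuses_supplied_variance_components(self, small_geno, null_panel):
        vc = {t: VarianceComponents(0.0, 1.0, 0.0, 0.0, True) for t in null_panel.traits}
        res = run_gwas(small_geno, null_panel, vc=vc)
        assert res.variance_components["trait00"].sigma2_e == 1.0

    def test_sample_mismatch_raises(self, small_geno, null_panel):
        bad = TraitPanel(null_panel.values, null_panel.traits, null_panel.key_trait,
                         ["x" + s for s in small_geno.individuals])
        with pytest.raises(ValueError, match="identifiers"):
            MlmaGwas(bad, small_geno)


class TestWaldAndBonferroni:
    @pytest.mark.parametrize("effect,se,expected,tol", [
        (0.0, 1.0, 0.0, 1e-12),
        (1.959964, 1.0, 1.3010, 1e-3),
        (29.5, 0.951, 210.5, 0.2),
    ])
    def test_reference_values(self, effect, se, expected, tol):
        assert wald_neglog10p(effect, se) == pytest.approx(expected, abs=tol)

    def test_large_statistics_stay_finite(self):
        assert np.isfinite(wald_neglog10p(1e6, 1e-3))

    @given(st.floats(0.01, 50), st.floats(0.01, 50))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_abs_effect(self, a, b):
        lo, hi = sorted([a, b])
        if hi > lo:
            assert wald_neglog10p(hi, 1.0) > wald_neglog10p(lo, 1.0)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            wald_neglog10p(1.0, 0.0)

    @pytest.mark.parametrize("n,alpha,p_exp", [(1, 0.05, 0.05), (10, 0.05, 0.005)])
    def test_bonferroni_simple(self, n, alpha, p_exp):
        p, nlp = bonferroni_threshold(n, alpha)
        assert p == pytest.approx(p_exp)
        assert nlp == pytest.approx(-np.log10(p_exp))

    def test_bonferroni_paper_scale(self):
        p, nlp = bonferroni_threshold(8_551_748, 0.05)
        assert float(f"{p:.1e}") == 5.8e-09
        assert round(nlp, 1) == 8.2
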