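import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mtburden.univariate import (
    fit_trait_association,
    inverse_normal_transform,
    permutation_score_columns,
    z_matrix,
    z_vector,
)
from conftest import make_phenotypes


class TestFit:
    def test_orthogonal_score_gives_zero_t(self, rng):
        # score constructed orthogonal to the covariate-residualized trait
        n = 40
        cov = rng.normal(size=n)
        trait = rng.normal(size=n)
        X = np.column_stack([np.ones(n), cov])
        e_trait = trait - X @ np.linalg.lstsq(X, trait, rcond=None)[0]
        u = e_trait / np.linalg.norm(e_trait)
        score = rng.normal(size=n)
        score -= u * (u @ score)
        t, _ = fit_trait_association(score, trait, "quantitative", cov)
        assert t == pytest.approx(0.0, abs=1e-8)

    def test_perfect_fit_is_degenerate(self, rng):
        score = rng.normal(size=6)
        t, df = fit_trait_association(score, 2.0 * score, "quantitative",
                                      np.empty((6, 0)))
        assert np.isnan(t)

    def test_zero_variance_score_is_degenerate(self):
        t, _ = fit_trait_association(np.ones(10), np.arange(10.0),
                                     "quantitative", np.empty((10, 0)))
        assert np.isnan(t)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_ols_t_matches_statsmodels(self, seed):
        import statsmodels.api as sm

        rng = np.random.default_rng(seed)
        n = 80
        cov = rng.normal(size=(n, 2))
        score = rng.normal(size=n)
        trait = 0.3 * score + cov @ [0.5, -0.2] + rng.normal(size=n)
        t, df = fit_trait_association(score, trait, "quantitative", cov)
        X = sm.add_constant(np.column_stack([cov, score]))
        fit = sm.OLS(trait, X).fit()
        assert t == pytest.approx(fit.tvalues[-1], rel=1e-9)
        assert df == fit.df_resid

    @pytest.mark.parametrize("seed", [3, 4])
    def test_logistic_wald_matches_statsmodels(self, seed):
        import statsmodels.api as sm

        rng = np.random.default_rng(seed)
        n = 300
        cov = rng.normal(size=(n, 2))
        score = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(-0.5 + 0.4 * score + cov @ [0.3, -0.3])))
        y = rng.binomial(1, p).astype(float)
        z, df = fit_trait_association(score, y, "binary", cov)
        X = sm.add_constant(np.column_stack([cov, score]))
        fit = sm.Logit(y, X).fit(disp=0, tol=1e-10)
        assert z == pytest.approx(fit.tvalues[-1], rel=1e-5)
        assert np.isinf(df)

    def test_separated_binary_trait_degrades_to_nan(self):
        score = np.arange(20.0)
        y = (score > 9.5).astype(float)  # perfect separation
        z, _ = fit_trait_association(score, y, "binary", np.empty((20, 0)))
        assert np.isnan(z)

    def test_missing_trait_values_use_complete_cases(self, rng):
        n = 60
        score = rng.normal(size=n)
        trait = 0.5 * score + rng.normal(size=n)
        trait_na = trait.copy()
        trait_na[:10] = np.nan
        t_full, _ = fit_trait_association(score[10:], trait[10:], "quantitative",
                                          np.empty((50, 0)))
        t_na, _ = fit_trait_association(score, trait_na, "quantitative",
                                        np.empty((n, 0)))
        assert t_na == pytest.approx(t_full, rel=1e-12)


class TestInverseNormalTransform:
    def test_zero_maps_to_zero(self):
        assert inverse_normal_transform(0.0, 7) == pytest.approx(0.0, abs=1e-14)

    def test_t_cdf_quantile_example(self):
        # Phi^-1(F_t(2.0; 10)) computed independently from scipy's t CDF
        expected = stats.norm.ppf(stats.t.cdf(2.0, 10))
        got = inverse_normal_transform(2.0, 10)
        assert got == pytest.approx(expected, abs=1e-10)
        assert got == pytest.approx(1.79041, abs=1e-5)

    def test_large_df_converges_to_identity(self):
        assert inverse_normal_transform(1.5, 1e6) == pytest.approx(1.5, abs=1e-3)

    def test_asymptotic_flag_is_identity(self):
        assert inverse_normal_transform(2.34, None) == 2.34
        assert inverse_normal_transform(2.34, np.inf) == pytest.approx(2.34, abs=1e-9)

    def test_extreme_statistic_stays_finite(self):
        z = inverse_normal_transform(80.0, 100)
        assert np.isfinite(z) and z > 8

    def test_nonpositive_df_rejected(self):
        with pytest.raises(ValueError):
            inverse_normal_transform(1.0, 0)

    @settings(deadline=None, max_examples=60)
    @given(st.floats(-30, 30), st.floats(1, 200))
    def test_antisymmetry(self, t, df):
        a = inverse_normal_transform(t, df)
        b = inverse_normal_transform(-t, df)
        assert a == pytest.approx(-b, abs=1e-10)

    @settings(deadline=None, max_examples=60)
    @given(st.floats(-20, 20), st.floats(-20, 20), st.floats(2, 100))
    def test_monotonicity(self, t1, t2, df):
        lo, hi = sorted([t1, t2])
        if hi - lo < 1e-9:
            return
        assert inverse_normal_transform(lo, df) < inverse_normal_transform(hi, df)


class TestNullDistributions:
    def test_null_t_follows_t_distribution(self, rng):
        # trait independent of score; many permuted score columns share the
        # null distribution of independent replicates
        n = 200
        trait = rng.normal(size=n)
        score = rng.gamma(2.0, size=n)
        pheno = make_phenotypes(trait[:, None], ["quantitative"])
        S = permutation_score_columns(score, 1000, rng)
        from mtburden.univariate import _ols_t_batch

        t, df = _ols_t_batch(trait, np.ones((n, 1)), S)
        assert df == n - 2
        assert stats.kstest(t, "t", args=(df,)).pvalue > 0.01

    def test_null_z_is_standard_normal(self, rng):
        n = 500
        traits = np.column_stack([rng.normal(size=n), rng.normal(size=n)])
        pheno = make_phenotypes(traits, ["quantitative", "quantitative"],
                                covariates=rng.normal(size=(n, 2)))
        score = rng.gamma(1.0, size=n)
        S = permutation_score_columns(score, 2000, rng)
        Z = z_matrix(S, pheno)
        for l in range(2):
            assert stats.kstest(Z[:, l], "norm").pvalue > 0.01


def test_z_vector_pvalues_match_normal_two_sided(rng):
    n = 120
    traits = np.column_stack([rng.normal(size=n),
                              rng.binomial(1, 0.4, size=n).astype(float)])
    pheno = make_phenotypes(traits, ["quantitative", "binary"],
                            covariates=rng.normal(size=(n, 1)))
    score = rng.poisson(1.0, size=n).astype(float)
    zv = z_vector(score, pheno)
    assert np.all(np.isfinite(zv.z))
    np.testing.assert_allclose(zv.per_trait_p,
                               2 * stats.norm.sf(np.abs(zv.z)), atol=1e-12)
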