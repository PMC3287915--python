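import numpy as np
import pytest
from scipy import stats

from mtburden.cmt import (
    DegenerateStatistic,
    SigmaEstimate,
    _conditioned,
    cmt_linear,
    cmt_quadratic,
    estimate_sigma,
)
from mtburden.gene_score import weighted_sum_scores
from mtburden.univariate import fit_trait_association, inverse_normal_transform
from conftest import make_genotypes, make_phenotypes


def random_correlation(m, rng):
    A = rng.normal(size=(m, m + 2))
    S = A @ A.T
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


class TestQuadratic:
    def test_zero_z_gives_zero_stat_p_one(self):
        t, p = cmt_quadratic(np.zeros(3), np.eye(3))
        assert t == 0 and p == pytest.approx(1.0)

    def test_identity_sigma_example(self):
        t, p = cmt_quadratic(np.array([1.96, 0.0]), np.eye(2))
        assert t == pytest.approx(3.8416)
        assert p == pytest.approx(0.1465, abs=2e-4)

    def test_m1_reduces_to_squared_normal(self):
        z = 1.234
        t, p = cmt_quadratic(np.array([z]), np.eye(1))
        assert t == pytest.approx(z**2, abs=1e-12)
        assert p == pytest.approx(2 * stats.norm.sf(abs(z)), abs=1e-12)

    @pytest.mark.parametrize("m", [2, 3, 4, 5, 6])
    def test_solve_matches_explicit_inverse(self, m, rng):
        for _ in range(50):
            sigma = random_correlation(m, rng)
            z = rng.normal(size=m)
            t, _ = cmt_quadratic(z, sigma)
            brute = z @ np.linalg.inv(sigma) @ z
            assert t == pytest.approx(brute, abs=1e-10 * max(1.0, brute))

    def test_sign_flip_invariance_under_diagonal_sigma(self, rng):
        z = rng.normal(size=4)
        t0, _ = cmt_quadratic(z, np.eye(4))
        for _ in range(5):
            signs = rng.choice([-1.0, 1.0], size=4)
            t1, _ = cmt_quadratic(z * signs, np.eye(4))
            assert t1 == pytest.approx(t0, rel=1e-12)

    def test_nonfinite_z_raises(self):
        with pytest.raises(DegenerateStatistic):
            cmt_quadratic(np.array([np.nan, 0.0]), np.eye(2))

    def test_singular_sigma_is_regularized(self):
        sigma = np.ones((2, 2))  # perfectly correlated traits
        z = np.array([1.0, 1.0])
        t, p = cmt_quadratic(z, sigma)
        assert np.isfinite(t) and t >= 0 and 0 <= p <= 1


class TestLinear:
    def test_equal_z_identity_sigma(self):
        t, p = cmt_linear(np.ones(4), np.eye(4))
        assert t == pytest.approx(2.0)
        assert p == pytest.approx(2 * stats.norm.sf(2.0), abs=1e-12)

    def test_direction_cancellation(self):
        t, p = cmt_linear(np.array([1.7, -1.7]), np.eye(2))
        assert t == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_m1_reduces_to_z(self):
        t, p = cmt_linear(np.array([-0.77]), np.eye(1))
        assert t == pytest.approx(-0.77, abs=1e-12)
        assert p == pytest.approx(2 * stats.norm.sf(0.77), abs=1e-12)


class TestConditioning:
    def test_pd_matrix_untouched(self, rng):
        sigma = random_correlation(3, rng)
        out, flag = _conditioned(sigma)
        assert flag == "ok"
        np.testing.assert_array_equal(out, sigma)

    def test_rank_deficient_matrix_shrunk(self):
        sigma = np.ones((3, 3))
        out, flag = _conditioned(sigma)
        assert flag == "regularized"
        assert np.linalg.eigvalsh(out)[0] > 0


class TestEstimateSigma:
    @staticmethod
    def _dataset(rng, n=500, rho=0.0):
        d = rng.binomial(2, rng.uniform(0.02, 0.2, size=8), size=(n, 8))
        score = weighted_sum_scores(make_genotypes(d)).scores
        R = np.array([[1.0, rho], [rho, 1.0]])
        traits = rng.multivariate_normal(np.zeros(2), R, size=n)
        return score, make_phenotypes(traits, ["quantitative"] * 2)

    def test_independent_traits_have_small_offdiagonal(self, rng):
        score, pheno = self._dataset(rng)
        sig = estimate_sigma(score, pheno, 1000, rng)
        assert sig.sigma_hat.shape == (2, 2)
        np.testing.assert_allclose(np.diag(sig.sigma_hat), 1.0)
        assert abs(sig.sigma_hat[0, 1]) < 0.1  # Fisher-z bound at N=1000, rho=0

    def test_duplicated_trait_gives_unit_correlation(self, rng):
        score, pheno = self._dataset(rng, n=300)
        pheno.traits[:, 1] = pheno.traits[:, 0]
        sig = estimate_sigma(score, pheno, 300, rng)
        assert sig.sigma_hat[0, 1] == pytest.approx(1.0, abs=1e-10)
        assert sig.condition_flag in ("regularized", "degenerate")

    def test_correlated_traits_match_independent_replicate_oracle(self, rng):
        # parallel Monte-Carlo oracle: correlation of Z across fresh null
        # datasets with the same trait correlation
        rho, n, n_orc = 0.6, 400, 400
        score, pheno = self._dataset(rng, n=n, rho=rho)
        sig = estimate_sigma(score, pheno, 2000, rng)
        R = np.array([[1.0, rho], [rho, 1.0]])
        zs = np.empty((n_orc, 2))
        for k in range(n_orc):
            traits = rng.multivariate_normal(np.zeros(2), R, size=n)
            for l in range(2):
                t, df = fit_trait_association(score, traits[:, l],
                                              "quantitative", np.empty((n, 0)))
                zs[k, l] = inverse_normal_transform(t, df)
        oracle = np.corrcoef(zs, rowvar=False)[0, 1]
        assert sig.sigma_hat[0, 1] == pytest.approx(oracle, abs=0.08)

    def test_constant_trait_raises_naming_it(self, rng):
        score, pheno = self._dataset(rng, n=200)
        pheno.traits[:, 1] = 3.14
        with pytest.raises(ValueError, match="Y2"):
            estimate_sigma(score, pheno, 200, rng)

    def test_single_trait_returns_trivial_identity(self, rng):
        score, pheno = self._dataset(rng, n=200)
        sig = estimate_sigma(score, pheno.subset_traits([0]), 200, rng)
        np.testing.assert_array_equal(sig.sigma_hat, [[1.0]])

    def test_permuted_z_retained_for_reuse(self, rng):
        score, pheno = self._dataset(rng, n=200)
        sig = estimate_sigma(score, pheno, 250, rng)
        assert sig.permuted_z is not None and sig.permuted_z.shape == (250, 2)

    def test_low_permutation_count_warns(self, rng):
        score, pheno = self._dataset(rng, n=200)
        with pytest.warns(UserWarning, match="low"):
            estimate_sigma(score, pheno, 50, rng)
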