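import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.integrate import quad
from scipy.special import ndtr

from latentcorr.model import (
    FeatureData,
    FeatureParams,
    Hyperparams,
    binom_probit_log_pmf,
    joint_log_posterior,
    latent_log_density,
    log_prior,
    scaled_beta_log_pdf,
    zip_log_pmf,
)


class TestZipLogPmf:
    def test_structural_zero_certainty(self):
        assert zip_log_pmf(0, 0.0, 1.0, 1.0) == pytest.approx(0.0)

    def test_positive_count_oracle(self):
        # independent route: scipy Poisson pmf plus the mixture weight
        expected = np.log(0.8) + stats.poisson.logpmf(2, 2.0)
        assert zip_log_pmf(2, np.log(2.0), 1.0, 0.2) == pytest.approx(expected)
        assert zip_log_pmf(2, np.log(2.0), 1.0, 0.2) == pytest.approx(-1.5300, abs=1e-4)

    def test_zero_count_oracle(self):
        expected = np.log(0.2 + 0.8 * np.exp(-1.0))
        assert zip_log_pmf(0, 0.0, 1.0, 0.2) == pytest.approx(expected)
        assert zip_log_pmf(0, 0.0, 1.0, 0.2) == pytest.approx(-0.7046, abs=1e-4)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            zip_log_pmf(-1, 0.0, 1.0, 0.2)
        with pytest.raises(ValueError):
            zip_log_pmf(1, 0.0, 0.0, 0.2)
        with pytest.raises(ValueError):
            zip_log_pmf(1, 0.0, 1.0, 1.5)

    @given(
        x=st.floats(-3.0, 4.0),
        s=st.floats(0.2, 3.0),
        pi=st.floats(0.0, 1.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_normalizes_to_one(self, x, s, pi):
        rate = s * np.exp(x)
        y_max = int(rate + 12 * np.sqrt(rate) + 60)
        total = np.sum(np.exp(zip_log_pmf(np.arange(y_max + 1), x, s, pi)))
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_pi_zero_is_plain_poisson(self):
        for y in range(6):
            assert zip_log_pmf(y, 0.7, 1.3, 0.0) == pytest.approx(
                stats.poisson.logpmf(y, 1.3 * np.exp(0.7))
            )


class TestBinomProbitLogPmf:
    def test_half_probability(self):
        assert binom_probit_log_pmf(1, 0.0, 2) == pytest.approx(np.log(0.5))

    def test_empty_coverage_is_vacuous(self):
        assert binom_probit_log_pmf(0, 12.3, 0) == pytest.approx(0.0)
        assert binom_probit_log_pmf(0, -50.0, 0) == pytest.approx(0.0)

    def test_oracle_value(self):
        p = ndtr(1.0)
        expected = np.log(3 * p**2 * (1 - p))
        assert binom_probit_log_pmf(2, 1.0, 3) == pytest.approx(expected)
        assert binom_probit_log_pmf(2, 1.0, 3) == pytest.approx(-1.0879, abs=1e-4)

    def test_matches_scipy_binom(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(1, 30))
            y = int(rng.integers(0, n + 1))
            x = float(rng.normal())
            assert binom_probit_log_pmf(y, x, n) == pytest.approx(
                stats.binom.logpmf(y, n, ndtr(x))
            )

    def test_extreme_latent_is_finite(self):
        assert np.isfinite(binom_probit_log_pmf(3, -40.0, 10))
        assert np.isfinite(binom_probit_log_pmf(7, 40.0, 10))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            binom_probit_log_pmf(3, 0.0, 2)
        with pytest.raises(ValueError):
            binom_probit_log_pmf(-1, 0.0, 2)

    @given(x=st.floats(-6.0, 6.0), n=st.integers(1, 30))
    @settings(max_examples=25, deadline=None)
    def test_normalizes_to_one(self, x, n):
        total = np.sum(np.exp(binom_probit_log_pmf(np.arange(n + 1), x, n)))
        assert total == pytest.approx(1.0, abs=1e-10)


class TestLatentLogDensity:
    def test_independent_standard_normals_at_mode(self):
        params = FeatureParams(0.0, 0.0, 1.0, 1.0, 0.0, 0.0)
        assert latent_log_density((0.0, 0.0), params) == pytest.approx(
            -np.log(2 * np.pi)
        )

    def test_correlated_mode_value(self):
        params = FeatureParams(0.0, 0.0, 1.0, 1.0, 0.5, 0.0)
        expected = -np.log(2 * np.pi) - 0.5 * np.log(0.75)
        assert latent_log_density((0.0, 0.0), params) == pytest.approx(expected)
        assert latent_log_density((0.0, 0.0), params) == pytest.approx(
            -1.6940, abs=1e-4
        )

    def test_rho_zero_factorizes(self):
        params = FeatureParams(0.7, -0.2, 1.4, 0.6, 0.0, 0.0)
        x = (0.5, -1.1)
        expected = stats.norm.logpdf(x[0], 0.7, 1.4) + stats.norm.logpdf(
            x[1], -0.2, 0.6
        )
        assert latent_log_density(x, params) == pytest.approx(expected)

    def test_singular_covariance_rejected(self):
        with pytest.raises(ValueError):
            FeatureParams(0.0, 0.0, 1.0, 1.0, 1.0, 0.0)


class TestLogPrior:
    def test_out_of_support_rho(self, hyper):
        params = FeatureParams(0.0, 0.0, 1.0, 1.0, 0.0, 0.2)
        params.rho = 1.5  # bypass constructor validation
        assert log_prior(params, hyper) == -np.inf

    def test_scaled_beta_at_zero(self, hyper):
        expected = np.log(0.5 * stats.beta.pdf(0.5, 15, 15))
        assert scaled_beta_log_pdf(0.0, 15, 15) == pytest.approx(expected)

    def test_scaled_beta_symmetry(self):
        for rho in (0.1, 0.35, 0.8):
            assert scaled_beta_log_pdf(rho, 15, 15) == pytest.approx(
                scaled_beta_log_pdf(-rho, 15, 15)
            )

    def test_scaled_beta_integrates_to_one(self):
        total, _ = quad(lambda r: np.exp(scaled_beta_log_pdf(r, 15, 15)), -1, 1)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_scaled_beta_mean_zero_when_symmetric(self):
        mean, _ = quad(
            lambda r: r * np.exp(scaled_beta_log_pdf(r, 15, 15)), -1, 1
        )
        assert mean == pytest.approx(0.0, abs=1e-9)
        assert Hyperparams().rho_prior_mean() == 0.0

    def test_prior_is_sum_of_components(self, hyper):
        params = FeatureParams(3.5, 0.2, 1.1, 0.9, 0.3, 0.25)
        expected = (
            stats.beta.logpdf(0.25, 2, 8)
            + stats.multivariate_normal.logpdf([3.5, 0.2], hyper.m, hyper.H)
            + stats.invgamma.logpdf(1.1, 2.5, scale=4.5)
            + stats.invgamma.logpdf(0.9, 2.5, scale=4.5)
            + scaled_beta_log_pdf(0.3, 15, 15)
        )
        assert log_prior(params, hyper) == pytest.approx(expected)


class TestJointLogPosterior:
    def test_additivity_oracle(self, toy_feature, toy_params, hyper):
        # brute-force term-by-term re-evaluation
        total = log_prior(toy_params, hyper)
        for i in range(toy_feature.n_cells):
            total += zip_log_pmf(
                int(toy_feature.y1[i]),
                toy_params.X[i, 0],
                toy_feature.s[i],
                toy_params.pi,
            )
            total += binom_probit_log_pmf(
                int(toy_feature.y2[i]), toy_params.X[i, 1], int(toy_feature.n[i])
            )
            total += latent_log_density(toy_params.X[i], toy_params)
        assert joint_log_posterior(toy_feature, toy_params, hyper) == pytest.approx(
            total
        )

    def test_permutation_invariance(self, toy_feature, toy_params, hyper, rng):
        order = rng.permutation(toy_feature.n_cells)
        permuted = toy_feature.permuted(order)
        permuted_params = FeatureParams(
            toy_params.mu1,
            toy_params.mu2,
            toy_params.sigma1,
            toy_params.sigma2,
            toy_params.rho,
            toy_params.pi,
            X=toy_params.X[order],
        )
        assert joint_log_posterior(
            permuted, permuted_params, hyper
        ) == pytest.approx(joint_log_posterior(toy_feature, toy_params, hyper))

    def test_zero_counts_monotone_in_pi(self, hyper, rng):
        I = 10
        data = FeatureData(
            "zeros", np.zeros(I, int), np.zeros(I, int), np.zeros(I, int), np.ones(I)
        )
        X = rng.normal(0, 1, (I, 2))
        lls = []
        for pi in (0.1, 0.4, 0.8):
            lls.append(
                np.sum(zip_log_pmf(data.y1, X[:, 0], data.s, pi))
            )
        assert lls[0] < lls[1] < lls[2]

    def test_dimension_mismatch(self, toy_feature, hyper, rng):
        params = FeatureParams(
            1.0, 0.0, 1.0, 1.0, 0.0, 0.1, X=rng.normal(size=(5, 2))
        )
        with pytest.raises(ValueError):
            joint_log_posterior(toy_feature, params, hyper)


class TestFeatureData:
    def test_validation(self):
        with pytest.raises(ValueError):
            FeatureData("bad", [1, 2], [3, 1], [2, 2], [1.0, 1.0])  # y2 > n
        with pytest.raises(ValueError):
            FeatureData("bad", [-1, 2], [0, 1], [2, 2], [1.0, 1.0])
        with pytest.raises(ValueError):
            FeatureData("bad", [1, 2], [0, 1], [2, 2], [0.0, 1.0])
        with pytest.raises(ValueError):
            FeatureData("bad", [1], [0], [2], [1.0])  # single cell


class TestHyperparams:
    def test_defaults_match_documented_values(self):
        h = Hyperparams()
        assert (h.a, h.b) == (2.0, 8.0)
        assert (h.c1, h.c2) == (2.5, 4.5)
        assert (h.d1, h.d2) == (15.0, 15.0)
        np.testing.assert_array_equal(h.m, [4.0, 0.0])
        np.testing.assert_array_equal(h.H, np.eye(2))

    def test_rejects_bad_H(self):
        with pytest.raises(ValueError):
            Hyperparams(H=np.array([[1.0, 2.0], [2.0, 1.0]]))  # not PD
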