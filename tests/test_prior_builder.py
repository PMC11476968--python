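import numpy as np
import pytest
from scipy import stats

from ctsmeqtl import (
    PriorEstimate,
    build_prior,
    build_snp_priors,
    estimate_cts_effect,
    estimate_prior_correlation,
    shrinkage_weight,
    uninformative_prior,
)
from ctsmeqtl.prior_builder import adjust_pvalues
from ctsmeqtl.priors import default_rates, repair_correlation


class TestCtsEffect:
    def test_perfect_linear_relation(self):
        g = np.array([0.0, 0.0, 1.0, 1.0, 2.0, 2.0])
        beta, p = estimate_cts_effect(g.copy(), g)
        assert beta == pytest.approx(1.0)
        assert p < 1e-6

    def test_constant_genotype_returns_null(self):
        assert estimate_cts_effect([1.0, 2.0, 3.0, 4.0], np.ones(4)) == (0.0, 1.0)

    def test_all_missing_returns_null(self):
        beta, p = estimate_cts_effect([np.nan] * 5, np.arange(5.0) % 3)
        assert (beta, p) == (0.0, 1.0)

    def test_recovers_known_slope(self):
        rng = np.random.default_rng(8)
        g = rng.binomial(2, 0.4, 28).astype(float)
        y = 0.4 * g + rng.normal(0, 0.5, 28)
        beta, p = estimate_cts_effect(y, g)
        se = 0.5 / np.sqrt(28 * g.var())
        assert abs(beta - 0.4) < 3 * se

    def test_covariate_adjustment(self):
        rng = np.random.default_rng(3)
        g = rng.binomial(2, 0.3, 60).astype(float)
        c = rng.standard_normal(60)
        y = 0.5 * g + 2.0 * c + rng.normal(0, 0.1, 60)
        beta, _ = estimate_cts_effect(y, g, covariates=c)
        assert abs(beta - 0.5) < 0.05


class TestWeights:
    def test_bonferroni_capped(self):
        assert shrinkage_weight(0.04, n_tests=100) == 0.0

    def test_bonferroni_arithmetic(self):
        assert shrinkage_weight(1e-6, n_tests=100) == pytest.approx(0.9999)

    def test_bh_stepup_hand_oracle(self):
        p = np.array([0.001, 0.01, 0.03, 0.8])
        np.testing.assert_allclose(
            adjust_pvalues(p, method="bh"), [0.004, 0.02, 0.04, 0.8]
        )
        np.testing.assert_allclose(
            shrinkage_weight(p, method="bh"), [0.996, 0.98, 0.96, 0.2]
        )

    def test_weight_antitone_in_adjusted_p(self):
        ps = np.linspace(0, 1, 11)
        ws = [shrinkage_weight(p, n_tests=1) for p in ps]
        assert all(a >= b for a, b in zip(ws, ws[1:]))


class TestPriorCorrelation:
    def test_identical_vectors(self):
        x = np.arange(10.0)
        r, p = estimate_prior_correlation(x, x)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_too_few_samples(self):
        assert estimate_prior_correlation([1.0, 2.0], [2.0, 1.0]) == (0.0, 1.0)

    def test_recovers_known_correlation(self):
        rng = np.random.default_rng(12)
        cov = [[1.0, 0.5], [0.5, 1.0]]
        xy = rng.multivariate_normal([0, 0], cov, 28)
        r, _ = estimate_prior_correlation(xy[:, 0], xy[:, 1])
        fisher_se = 1.0 / np.sqrt(25)
        assert abs(np.arctanh(r) - np.arctanh(0.5)) < 3 * fisher_se

    def test_null_correlation_rarely_extreme(self):
        rng = np.random.default_rng(99)
        ok = 0
        for _ in range(1000):
            a, b = rng.standard_normal((2, 28))
            r, p = estimate_prior_correlation(a, b)
            ok += (abs(r) < 0.5) and (p > 0.01)
        assert ok >= 950


class TestBuildPrior:
    def test_zero_weights_reduce_to_uninformative(self):
        ests = [PriorEstimate(beta_seq=0.8, p_raw=1.0, p_adjust=1.0)] * 3
        prior = build_prior(ests)
        ref = uninformative_prior(3)
        assert np.array_equal(prior.mu, ref.mu)
        assert np.array_equal(prior.rho, ref.rho)

    def test_high_correlations_stay_positive_definite(self):
        ests = [PriorEstimate(beta_seq=0.2, p_raw=0.0, p_adjust=0.0)] * 3
        corr = {(j, k): (0.99, 1.0) for j in range(3) for k in range(j + 1, 3)}
        prior = build_prior(ests, corr)
        assert np.linalg.eigvalsh(prior.rho).min() >= 1e-8
        np.testing.assert_allclose(np.diag(prior.rho), 1.0)

    def test_nonpd_matrix_repaired_to_clipping_oracle(self):
        corr = {(0, 1): (0.9, 1.0), (0, 2): (0.9, 1.0), (1, 2): (-0.9, 1.0)}
        ests = [PriorEstimate(beta_seq=0.0, p_raw=0.0, p_adjust=0.0)] * 3
        prior = build_prior(ests, corr)
        assert np.linalg.eigvalsh(prior.rho).min() >= 1e-8
        np.testing.assert_allclose(np.diag(prior.rho), 1.0, atol=1e-12)
        # oracle: clip eigenvalues at the floor, rescale to unit diagonal
        A = np.array([[1, 0.9, 0.9], [0.9, 1, -0.9], [0.9, -0.9, 1.0]])
        vals, vecs = np.linalg.eigh(A)
        clipped = (vecs * np.clip(vals, 1e-8, None)) @ vecs.T
        d = np.sqrt(np.diag(clipped))
        oracle = clipped / np.outer(d, d)
        np.testing.assert_allclose(prior.rho, oracle, atol=0.02)

    def test_missing_celltypes_get_zero_mean(self):
        prior = build_prior(
            {0: PriorEstimate(beta_seq=0.5, p_raw=1e-9, p_adjust=1e-7)},
            n_celltypes=3,
        )
        assert prior.mu[0] == pytest.approx(0.5, rel=1e-4)
        assert prior.mu[1] == prior.mu[2] == 0.0

    def test_per_snp_priors_track_true_effects(self):
        rng = np.random.default_rng(21)
        m, p = 200, 5
        G = rng.binomial(2, 0.3, (m, p)).astype(float)
        cts = np.column_stack(
            [0.6 * G[:, 0] + rng.normal(0, 0.5, m)]
            + [rng.standard_normal(m) for _ in range(2)]
        )
        priors = build_snp_priors(cts, G, n_tests=p)
        assert priors[0].mu[0] == pytest.approx(0.6, abs=0.15)
        assert abs(priors[1].mu[0]) < 0.2
        assert all(np.all(np.isfinite(pr.mu)) for pr in priors)


class TestPriorUtilities:
    def test_repair_correlation_identity_passthrough(self):
        R = np.eye(4)
        assert np.array_equal(repair_correlation(R), R)

    def test_default_rates_policy(self):
        rates = default_rates([0.2, 0.03, 0.075])
        assert rates[0] == pytest.approx(0.2)
        assert rates[1] == pytest.approx(5.0)
        assert 0.2 < rates[2] < 5.0
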