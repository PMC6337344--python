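import numpy as np
import pytest

from msagauss import (
    MSA,
    SingularModelError,
    binary20_encoding,
    build_prior,
    corrected_covariance,
    coupling_matrix,
    encode_msa,
    fit_gaussian_model,
    gaussian_log_likelihood,
    weighted_mean_cov,
)
from msagauss.encodings import Encoding
from msagauss.gaussian_model import PriorSpec
from msagauss.synthetic_data import SyntheticSpec, generate_msa
from msagauss.weighting import sequence_weights


def one_d_encoding(values):
    return Encoding(label="test1d", matrix=np.asarray(values, dtype=float).reshape(20, 1))


PM_ONE = one_d_encoding([1.0, -1.0] + [0.0] * 18)  # A -> 1, C -> -1


class TestWeightedMeanCov:
    def test_uniform_weights_reduce_to_unweighted(self):
        spec = SyntheticSpec(L=12, N=40, planted_pairs=[(1, 7)], seed=3)
        msa, _ = generate_msa(spec)
        encoded = encode_msa(msa, binary20_encoding())
        xbar_u, cbar_u = weighted_mean_cov(encoded)  # uniform by default
        xbar_w, cbar_w = weighted_mean_cov(encoded, np.full(msa.N, 1.0 / msa.N))
        assert np.allclose(xbar_u, xbar_w) and np.allclose(cbar_u, cbar_w)
        # direct unweighted formula as oracle
        assert np.allclose(xbar_u, encoded.X.mean(axis=0))
        xc = encoded.X - encoded.X.mean(axis=0)
        assert np.allclose(cbar_u, xc.T @ xc / msa.N)

    def test_single_sequence_zero_covariance(self):
        encoded = encode_msa(MSA(sequences=["ACD"]), binary20_encoding())
        _, cbar = weighted_mean_cov(encoded)
        assert np.all(cbar == 0)

    def test_two_sequence_closed_form(self):
        # "A","C" under A->1, C->-1 with equal weights: mean 0, variance 1
        encoded = encode_msa(MSA(sequences=["A", "C"]), PM_ONE)
        xbar, cbar = weighted_mean_cov(encoded)
        assert xbar == pytest.approx([0.0])
        assert np.allclose(cbar, [[1.0]])

    def test_weighting_result_accepted(self):
        msa = MSA(sequences=["AAAA", "AAAA", "CCCC"])
        encoded = encode_msa(msa, PM_ONE)
        w = sequence_weights(msa, r=0.5)  # weights (.5,.5,1) -> mean 0
        xbar, _ = weighted_mean_cov(encoded, w)
        assert np.allclose(xbar, 0.0)

    def test_covariance_psd(self):
        spec = SyntheticSpec(L=10, N=30, planted_pairs=[(1, 6)], seed=5)
        msa, _ = generate_msa(spec)
        _, cbar = weighted_mean_cov(encode_msa(msa, binary20_encoding()))
        eigs = np.linalg.eigvalsh(cbar)
        assert eigs.min() > -1e-10


class TestPrior:
    def test_binary20_closed_form(self):
        prior = build_prior(binary20_encoding(), L=4)
        assert np.allclose(prior.r_bar, 0.05)
        expected = np.full((20, 20), -0.0025)
        np.fill_diagonal(expected, 0.0475)
        assert np.allclose(prior.c_r, expected, atol=1e-15)

    def test_1d_prior_is_population_moments(self):
        values = np.arange(1.0, 21.0)
        prior = build_prior(one_d_encoding(values), L=2)
        assert prior.r_bar == pytest.approx([values.mean()])
        assert np.allclose(prior.c_r, [[values.var()]])

    def test_block_structure(self):
        prior = build_prior(binary20_encoding(), L=3)
        cp = prior.cp
        assert cp.shape == (60, 60)
        assert np.array_equal(cp[:20, :20], prior.c_r)
        assert not cp[:20, 20:40].any()  # off-diagonal position blocks zero
        assert np.array_equal(prior.mu, np.tile(prior.r_bar, 3))


class TestCorrectedCovariance:
    def test_endpoints_exact(self):
        spec = SyntheticSpec(L=8, N=25, planted_pairs=[(2, 8)], seed=7)
        msa, _ = generate_msa(spec)
        encoded = encode_msa(msa, binary20_encoding())
        prior = build_prior(encoded.encoding, msa.L)
        xbar, cbar = weighted_mean_cov(encoded)
        assert np.array_equal(corrected_covariance(xbar, cbar, prior, 0.0), cbar)
        assert np.array_equal(corrected_covariance(xbar, cbar, prior, 1.0), prior.cp)

    def test_scalar_interpolation(self):
        # CP=0.25, Cbar=1, Xbar=0, muP=0, lambda=0.5 -> 0.625
        prior = PriorSpec(r_bar=np.zeros(1), c_r=np.array([[0.25]]), L=1)
        cm = corrected_covariance(np.zeros(1), np.array([[1.0]]), prior, 0.5)
        assert np.allclose(cm, [[0.625]])

    def test_rank_one_mean_term(self):
        prior = PriorSpec(r_bar=np.zeros(1), c_r=np.zeros((1, 1)), L=1)
        cm = corrected_covariance(np.array([2.0]), np.zeros((1, 1)), prior, 0.5)
        assert np.allclose(cm, [[0.25 * 4.0]])  # lam(1-lam)*(xbar-mu)^2

    def test_lambda_out_of_range(self):
        prior = PriorSpec(r_bar=np.zeros(1), c_r=np.zeros((1, 1)), L=1)
        with pytest.raises(ValueError, match="lambda"):
            corrected_covariance(np.zeros(1), np.zeros((1, 1)), prior, 1.5)


class TestCouplingMatrix:
    def test_diagonal_inverse(self):
        d = np.array([1.0, 2.0, 4.0])
        J, eps = coupling_matrix(np.diag(d))
        assert eps == 0.0
        assert np.allclose(J, np.diag(1.0 / d))

    def test_inverse_residual_small(self):
        rng = np.random.default_rng(11)
        A = rng.normal(size=(50, 50))
        cm = A @ A.T + 50 * np.eye(50)
        J, eps = coupling_matrix(cm)
        assert eps == 0.0
        assert np.abs(J @ cm - np.eye(50)).max() < 1e-10

    def test_gap_free_binary20_is_singular_without_ridge(self):
        # each position block of a gap-free one-hot model has an exact
        # all-ones null direction
        spec = SyntheticSpec(L=8, N=200, planted_pairs=[(1, 7)], gap_rate=0.0, seed=2)
        msa, _ = generate_msa(spec)
        encoded = encode_msa(msa, binary20_encoding())
        prior = build_prior(encoded.encoding, msa.L)
        xbar, cbar = weighted_mean_cov(encoded)
        cm = corrected_covariance(xbar, cbar, prior, 0.5)
        # oracle: rank deficiency is exactly one null direction per position
        rank = np.linalg.matrix_rank(cm, tol=1e-10)
        assert rank <= cm.shape[0] - msa.L
        with pytest.raises(SingularModelError):
            coupling_matrix(cm, ridge="none")
        J, eps = coupling_matrix(cm, ridge="auto")
        assert eps > 0.0

    def test_explicit_ridge_value(self):
        cm = np.zeros((3, 3))
        J, eps = coupling_matrix(cm, ridge=0.5)
        assert eps == 0.5
        assert np.allclose(J, 2 * np.eye(3))


class TestLogLikelihood:
    def test_at_mean_identity_covariance(self):
        d = 6
        X = np.zeros((1, d))
        ll = gaussian_log_likelihood(X, np.zeros(d), np.eye(d))
        assert ll == pytest.approx(-(d / 2) * np.log(2 * np.pi))

    def test_maximized_at_empirical_moments(self):
        spec = SyntheticSpec(L=4, N=50, planted_pairs=[], gap_rate=0.0, seed=9)
        msa, _ = generate_msa(spec)
        encoded = encode_msa(msa, PM_ONE)
        xbar, cbar = weighted_mean_cov(encoded)
        cbar = cbar + 1e-6 * np.eye(cbar.shape[0])  # keep PD
        best = gaussian_log_likelihood(encoded, xbar, cbar)
        rng = np.random.default_rng(0)
        for _ in range(5):
            mu_p = xbar + rng.normal(0, 0.05, xbar.shape)
            sig_p = cbar + 0.05 * np.eye(cbar.shape[0])
            assert gaussian_log_likelihood(encoded, mu_p, cbar) < best
            assert gaussian_log_likelihood(encoded, xbar, sig_p) < best

    def test_doubling_sequences_doubles_loglik(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(7, 3))
        mu, sigma = np.zeros(3), np.eye(3) * 2.0
        single = gaussian_log_likelihood(X, mu, sigma)
        doubled = gaussian_log_likelihood(np.vstack([X, X]), mu, sigma)
        assert doubled == pytest.approx(2 * single)

    def test_non_pd_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            gaussian_log_likelihood(np.zeros((1, 2)), np.zeros(2), np.zeros((2, 2)))


class TestModelInvariants:
    def test_lambda_one_couplings_block_diagonal(self):
        # the uniform prior alone carries no inter-position information
        spec = SyntheticSpec(L=6, N=30, planted_pairs=[(1, 6)], seed=13)
        msa, _ = generate_msa(spec)
        encoded = encode_msa(msa, binary20_encoding())
        model = fit_gaussian_model(encoded, lam=1.0)
        J = model.J.reshape(msa.L, 20, msa.L, 20)
        for i in range(msa.L):
            for j in range(msa.L):
                if i != j:
                    assert np.abs(J[i, :, j, :]).max() == 0.0

    def test_binary20_mean_blocks_are_weighted_frequencies(self):
        msa = MSA(sequences=["AAAA", "AAAA", "CCCC"])
        encoded = encode_msa(msa, binary20_encoding())
        w = sequence_weights(msa, r=0.5)  # weights .5,.5,1 -> Meff 2
        xbar, cbar = weighted_mean_cov(encoded, w)
        # direct frequency counter oracle: A and C each weighted 1/2
        freq = np.zeros(20)
        freq[0] = 0.5  # A
        freq[1] = 0.5  # C
        for pos in range(4):
            block = xbar[pos * 20 : (pos + 1) * 20]
            assert np.allclose(block, freq)
            diag_block = cbar[pos * 20 : (pos + 1) * 20, pos * 20 : (pos + 1) * 20]
            assert np.allclose(diag_block, np.diag(freq) - np.outer(freq, freq))
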