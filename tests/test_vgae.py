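import numpy as np
import pytest

from spatialccc import vgae


class TestNormalizeAdjacency:
    def test_empty_graph_is_identity(self):
        np.testing.assert_allclose(vgae.normalize_adjacency(np.zeros((3, 3))),
                                   np.eye(3))

    def test_hand_computed_dag(self):
        A = np.array([[0, 1, 1], [0, 0, 1], [0, 0, 0]])
        expected = np.array([
            [1 / 3, 1 / 3, 1 / 3],
            [0, 1 / 2, 1 / 2],
            [0, 0, 1],
        ])
        np.testing.assert_allclose(vgae.normalize_adjacency(A), expected)

    def test_rows_sum_to_one_random(self, rng):
        for _ in range(50):
            n = rng.integers(1, 15)
            A = (rng.random((n, n)) < 0.4).astype(int)
            np.fill_diagonal(A, 0)
            rows = vgae.normalize_adjacency(A).sum(axis=1)
            np.testing.assert_allclose(rows, 1.0, atol=1e-9)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            vgae.normalize_adjacency(np.zeros((2, 3)))


def _params(rng, F=3, h=4, d=2):
    return vgae.EncoderParams(
        W0=rng.standard_normal((F, h)),
        W1_mu=rng.standard_normal((h, d)),
        W1_sigma=rng.standard_normal((h, d)),
    )


class TestEncode:
    def test_zero_features_zero_output(self, rng):
        p = _params(rng)
        A = vgae.normalize_adjacency((rng.random((5, 5)) < 0.5).astype(int))
        out = vgae.encode(A, np.zeros((5, 3)), p)
        np.testing.assert_array_equal(out.mu, 0.0)
        np.testing.assert_array_equal(out.log_sigma, 0.0)

    def test_single_node_hand_computation(self):
        # Ahat = [[1]], X = [[1]], W0 = [[2]], W1 = [[3]]: mu = relu(2) * 3 = 6
        p = vgae.EncoderParams(W0=np.array([[2.0]]),
                               W1_mu=np.array([[3.0, 0.0]]),
                               W1_sigma=np.array([[0.0, 0.0]]))
        out = vgae.encode(np.array([[1.0]]), np.array([[1.0]]), p)
        assert out.mu[0, 0] == pytest.approx(6.0)

    def test_permutation_equivariance_through_decoder(self, rng):
        n = 7
        A = (rng.random((n, n)) < 0.4).astype(int)
        np.fill_diagonal(A, 0)
        X = rng.standard_normal((n, 3))
        p = _params(rng)
        perm = rng.permutation(n)
        out = vgae.encode(vgae.normalize_adjacency(A), X, p)
        out_p = vgae.encode(vgae.normalize_adjacency(A[np.ix_(perm, perm)]),
                            X[perm], p)
        np.testing.assert_allclose(out_p.mu, out.mu[perm], atol=1e-12)
        # and end-to-end: decoded probabilities permute rows and columns
        P = vgae.decode_graph(out.mu)
        P_p = vgae.decode_graph(out_p.mu)
        np.testing.assert_allclose(P_p, P[np.ix_(perm, perm)], atol=1e-12)


class TestSampleLatent:
    def test_eval_mode_returns_mu_exactly(self, rng):
        enc = vgae.EncoderOutput(rng.standard_normal((4, 2)),
                                 rng.standard_normal((4, 2)))
        np.testing.assert_array_equal(vgae.sample_latent(enc, eval_mode=True),
                                      enc.mu)

    def test_degenerate_noise_collapses_to_mu(self, rng):
        mu = rng.standard_normal((4, 2))
        enc = vgae.EncoderOutput(mu, np.full((4, 2), -50.0))
        np.testing.assert_allclose(vgae.sample_latent(enc, seed=0), mu,
                                   atol=1e-12)

    def test_sample_mean_clt_bound(self):
        enc = vgae.EncoderOutput(np.zeros((10000, 2)), np.zeros((10000, 2)))
        Z = vgae.sample_latent(enc, seed=3)
        assert np.all(np.abs(Z.mean(axis=0)) < 0.05)

    def test_odd_latent_dim_rejected(self):
        enc = vgae.EncoderOutput(np.zeros((3, 3)), np.zeros((3, 3)))
        with pytest.raises(ValueError, match="even"):
            vgae.sample_latent(enc, seed=0)


class TestDecodeGraph:
    def test_zero_latents_give_half(self):
        np.testing.assert_array_equal(vgae.decode_graph(np.zeros((4, 6))), 0.5)

    def test_directed_asymmetry_hand_value(self):
        Z = np.array([[2.0, 0.0, 0.0, 0.0], [0.0, 0.0, 1.0, 0.0]])
        P = vgae.decode_graph(Z)
        assert P[0, 1] == pytest.approx(0.8808, abs=1e-4)  # sigma(2)
        assert P[1, 0] == pytest.approx(0.5)

    def test_source_negation_flips_probabilities(self, rng):
        Z = rng.standard_normal((6, 4))
        P = vgae.decode_graph(Z)
        Zf = Z.copy()
        Zf[:, :2] *= -1
        np.testing.assert_allclose(vgae.decode_graph(Zf), 1 - P, atol=1e-12)

    def test_matches_bruteforce_double_loop(self, rng):
        """Oracle: explicit logistic dot-products over every ordered pair."""
        for n in (1, 5, 20):
            d = 6
            Z = rng.standard_normal((n, d))
            P = vgae.decode_graph(Z)
            for i in range(n):
                for j in range(n):
                    dot = float(Z[i, : d // 2] @ Z[j, d // 2 :])
                    assert P[i, j] == pytest.approx(1 / (1 + np.exp(-dot)),
                                                    abs=1e-12)


class TestDecodeExpression:
    def test_zero_weights_zero_output(self, rng):
        dec = vgae.ExpressionDecoderParams(
            np.zeros((2, 3)), np.zeros(3), np.zeros((3, 5)), np.zeros(5)
        )
        out = vgae.decode_expression(rng.standard_normal((4, 2)), dec)
        np.testing.assert_array_equal(out, 0.0)
        assert out.shape == (4, 5)

    def test_single_unit_hand_computation(self):
        dec = vgae.ExpressionDecoderParams(
            np.ones((1, 1)), np.zeros(1), np.ones((1, 1)), np.zeros(1)
        )
        out = vgae.decode_expression(np.array([[2.0]]), dec)
        assert out[0, 0] == pytest.approx(2.0)  # relu(2) * 1


class TestKLDivergence:
    def test_prior_equals_posterior_is_zero(self):
        enc = vgae.EncoderOutput(np.zeros((5, 3)), np.zeros((5, 3)))
        assert vgae.kl_divergence(enc) == 0.0

    def test_closed_form_single_node(self):
        enc = vgae.EncoderOutput(np.array([[1.0]]), np.array([[0.0]]))
        assert vgae.kl_divergence(enc) == pytest.approx(0.5)

    def test_monotone_in_mean_magnitude(self):
        kls = [vgae.kl_divergence(
            vgae.EncoderOutput(np.array([[m]]), np.array([[0.0]])))
            for m in (0.0, 0.5, 1.0, 2.0)]
        assert all(a < b for a, b in zip(kls, kls[1:]))

    def test_matches_monte_carlo_estimate(self, rng):
        """KL closed form vs a 1e5-sample Monte-Carlo estimate (3 SE)."""
        mu = rng.standard_normal((2, 2)) * 0.5
        ls = rng.standard_normal((2, 2)) * 0.3
        enc = vgae.EncoderOutput(mu, ls)
        n_samp = 100_000
        sigma = np.exp(ls)
        z = mu[None] + sigma[None] * rng.standard_normal((n_samp, 2, 2))
        # log q(z) - log p(z), summed over nodes and dims, per-node mean
        log_q = (-0.5 * ((z - mu[None]) / sigma[None]) ** 2
                 - np.log(sigma[None]) - 0.5 * np.log(2 * np.pi))
        log_p = -0.5 * z**2 - 0.5 * np.log(2 * np.pi)
        samples = (log_q - log_p).sum(axis=(1, 2)) / mu.shape[0]
        mc = samples.mean()
        se = samples.std(ddof=1) / np.sqrt(n_samp)
        assert abs(vgae.kl_divergence(enc) - mc) < 3 * se
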