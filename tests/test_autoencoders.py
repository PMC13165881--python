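"""VAE and transformer autoencoder: closed forms, contracts, training."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from eeglatent.autoencoders import (
    LatentCodes,
    PosteriorParams,
    TaeConfig,
    TransformerAutoencoder,
    VaeConfig,
    VariationalAutoencoder,
    kl_gaussian,
    mha_forward,
    reconstruction_errors,
    tae_forward,
    train,
    vae_forward,
    vae_loss,
)
from eeglatent.session_io import zscore_matrix
from eeglatent.synth import CohortConfig, sample_cohort


class TestKlGaussian:
    def test_prior_equals_posterior(self):
        assert kl_gaussian(np.zeros(2), np.zeros(2)) == 0.0

    def test_unit_mean_shift(self):
        assert kl_gaussian(np.array([1.0, 0.0]), np.zeros(2)) == 0.5

    def test_inflated_variance(self):
        # sigma^2 = e per dim: KL = -1/2 * 2 * (1 + 1 - 0 - e) = e - 2
        val = kl_gaussian(np.zeros(2), np.ones(2))
        np.testing.assert_allclose(val, np.e - 2.0, rtol=1e-12)

    @given(
        st.lists(st.floats(-5, 5), min_size=2, max_size=2),
        st.lists(st.floats(-4, 3), min_size=2, max_size=2),
    )
    def test_nonnegative(self, mu, log_var):
        assert kl_gaussian(np.array(mu), np.array(log_var)) >= -1e-12

    def test_accepts_posterior_params_and_batches(self):
        pp = PosteriorParams(np.array([1.0, 0.0]), np.zeros(2))
        assert kl_gaussian(pp) == 0.5
        batch = kl_gaussian(np.array([[0.0, 0.0], [1.0, 0.0]]), np.zeros((2, 2)))
        np.testing.assert_allclose(batch, [0.0, 0.5])


def _vae_params(seed=0, cfg=None):
    model = VariationalAutoencoder(np.zeros((4, 10)), cfg or VaeConfig(seed=seed))
    return model._init_params(np.random.default_rng(seed))


class TestVaeForward:
    def test_zero_noise_returns_posterior_mean(self, rng):
        params = _vae_params()
        x = rng.normal(size=10)
        post, z, _ = vae_forward(x, params, noise=np.zeros(2))
        np.testing.assert_array_equal(z, post.mu)

    def test_zero_network_reconstructs_zero(self):
        params = {k: np.zeros_like(v.data) for k, v in _vae_params().items()}
        _, _, xhat = vae_forward(np.ones(10), params, noise=np.zeros(2))
        np.testing.assert_array_equal(xhat, np.zeros(10))

    def test_sampled_noise_varies_z_not_mu(self, rng):
        params = _vae_params()
        x = rng.normal(size=10)
        p1, z1, _ = vae_forward(x, params, rng=np.random.default_rng(1))
        p2, z2, _ = vae_forward(x, params, rng=np.random.default_rng(2))
        np.testing.assert_array_equal(p1.mu, p2.mu)
        assert not np.allclose(z1, z2)

    def test_noise_shape_checked(self):
        with pytest.raises(ValueError):
            vae_forward(np.zeros(10), _vae_params(), noise=np.zeros((3, 5)))


class TestVaeLoss:
    def test_decomposition_matches_independent_arithmetic(self, rng):
        """Loss equals the hand-computed sum of per-term definitions."""
        params = _vae_params(seed=3)
        X = rng.normal(size=(5, 10))
        total, recon, kl = vae_loss(X, params)
        post, _, xhat = vae_forward(X, params, noise=np.zeros((5, 2)))
        recon_hand = np.mean([np.sum((X[i] - xhat[i]) ** 2) for i in range(5)])
        kl_hand = np.mean(
            [kl_gaussian(post.mu[i], post.log_var[i]) for i in range(5)]
        )
        np.testing.assert_allclose(recon, recon_hand, rtol=1e-12)
        np.testing.assert_allclose(kl, kl_hand, rtol=1e-12)
        np.testing.assert_allclose(total, recon_hand + kl_hand, rtol=1e-12)


class TestTaeForward:
    def test_identical_tokens_give_uniform_attention(self, rng):
        E = 64
        params = {
            "w_q": rng.normal(size=(E, E)),
            "w_k": rng.normal(size=(E, E)),
            "w_v": rng.normal(size=(E, E)),
            "w_o": rng.normal(size=(E, E)),
        }
        tokens = np.tile(rng.normal(size=(1, 1, E)), (1, 10, 1))
        _, attn = mha_forward(tokens, params)
        np.testing.assert_allclose(attn, 1.0 / 10.0, atol=1e-12)

    def test_zero_network_outputs_bias(self):
        cfg = TaeConfig(seed=0)
        model = TransformerAutoencoder(np.zeros((4, 10)), cfg)
        params = {
            k: np.zeros_like(v.data)
            for k, v in model._init_params(np.random.default_rng(0)).items()
        }
        params["b_out"] = np.arange(10.0)
        z, xhat = tae_forward(np.ones(10), params, cfg)
        np.testing.assert_array_equal(z, np.zeros(16))
        np.testing.assert_array_equal(xhat, np.arange(10.0))

    def test_single_vector_mode_attention_is_identity_on_v(self, rng):
        E = 64
        params = {
            "w_q": rng.normal(size=(E, E)),
            "w_k": rng.normal(size=(E, E)),
            "w_v": rng.normal(size=(E, E)),
            "w_o": np.eye(E),
        }
        token = rng.normal(size=(1, 1, E))
        out, attn = mha_forward(token, params)
        np.testing.assert_allclose(attn, 1.0)
        np.testing.assert_allclose(out, token @ params["w_v"], rtol=1e-10)

    def test_unknown_token_mode_rejected(self):
        with pytest.raises(ValueError, match="token_mode"):
            TaeConfig(token_mode="bogus")

    def test_attention_permutation_equivariance(self, rng):
        """Permuting features + their token embeddings permutes MHA output."""
        cfg = TaeConfig(seed=0)
        model = TransformerAutoencoder(np.zeros((4, 10)), cfg)
        params = {
            k: v.data for k, v in model._init_params(np.random.default_rng(5)).items()
        }
        x = rng.normal(size=10)
        perm = rng.permutation(10)
        tokens = x[:, None] * params["w_embed"] + params["b_embed"]
        out, _ = mha_forward(tokens[None], params, cfg.heads, cfg.key_dim)
        out_perm, _ = mha_forward(tokens[None][:, perm], params, cfg.heads, cfg.key_dim)
        np.testing.assert_allclose(out[:, perm], out_perm, rtol=1e-10)


class TestTraining:
    def test_vae_loss_decreases_and_decomposes(self, vae_results):
        trace = vae_results.trace
        assert trace["total"].iloc[-1] < trace["total"].iloc[0]
        np.testing.assert_allclose(
            trace["total"], trace["recon"] + trace["kl"], atol=1e-8
        )

    def test_training_is_deterministic(self, cohort_std):
        _, codes1, trace1 = train("vae", cohort_std, VaeConfig(seed=9, epochs=20))
        _, codes2, trace2 = train("vae", cohort_std, VaeConfig(seed=9, epochs=20))
        assert trace1.equals(trace2)
        np.testing.assert_array_equal(codes1.codes, codes2.codes)

    def test_codes_align_with_cohort(self, tae_results, cohort_std):
        assert tae_results.codes.codes.shape == (cohort_std.n_sessions, 16)
        assert tae_results.codes.labels is not None
        assert len(tae_results.codes.labels) == cohort_std.n_sessions

    def test_tae_fits_near_noiseless_cohort(self):
        """Regression snapshot: planted structure is almost exactly learnable."""
        cfg = CohortConfig(noise_sd=1e-3, patient_sd=0.0, seed=1)
        std = zscore_matrix(sample_cohort(cfg))
        res = TransformerAutoencoder(std, TaeConfig(seed=1)).fit()
        assert res.trace["total"].iloc[-1] < 0.1

    def test_reconstruction_errors_match_hand_norms(self, tae_results, cohort_std):
        errs = tae_results.reconstruction_errors()
        xhat = tae_results.reconstruct()
        hand = np.sqrt(np.sum((cohort_std.values - xhat) ** 2, axis=1))
        np.testing.assert_allclose(errs, hand, rtol=1e-12)
        assert errs.shape == (cohort_std.n_sessions,)

    def test_functional_reconstruction_errors_examples(self):
        # x_hat == x and x_hat == x + unit vector, via a zero decoder trick
        X = np.zeros((2, 10))
        params = {k: np.zeros_like(v.data) for k, v in _vae_params().items()}
        np.testing.assert_array_equal(
            reconstruction_errors(params, X, "vae"), [0.0, 0.0]
        )
        params["b_dec2"] = np.eye(10)[0]  # x_hat = x + e1
        np.testing.assert_array_equal(
            reconstruction_errors(params, X, "vae"), [1.0, 1.0]
        )

    def test_unknown_model_kind(self, cohort_std):
        with pytest.raises(ValueError):
            train("gan", cohort_std)

    def test_raw_cohort_rejected(self, default_cfg):
        raw = sample_cohort(default_cfg)
        with pytest.raises(ValueError, match="standardized"):
            VariationalAutoencoder(raw)

    def test_summary_mentions_fit(self, vae_results):
        text = vae_results.summary()
        assert "Sessions:" in text and "Adam" in text
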