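"""VAE: posterior parameterization, KL, ELBO, training, latent export."""
import numpy as np
import pytest

from aculatent import (
    StateSpec, SyntheticConfig, TrainingError, elbo, embed_recording, encode,
    generate_latent_trajectory, init_vae, kl_gaussian, latent_trajectory,
    reconstruct, reconstruction_performance, reparameterize, train,
)
from aculatent.vae import LatentPosterior, LOG2PI, decode, stack_samples


def linear_identity_model(n=4, decoder_sign=1.0):
    """Hand-built linear model: encoder mean = x, decoder = +/- identity."""
    m = init_vae(n, n, hidden=(), seed=0)
    m.w_mu[:] = np.eye(n)
    m.b_mu[:] = 0.0
    m.w_lv[:] = 0.0
    m.b_lv[:] = 0.0  # sigma = 1
    w, b = m.dec_layers[-1]
    w[:] = decoder_sign * np.eye(n)
    b[:] = 0.0
    return m


def rank3_recordings(duration=20.0, n_recs=1, noise_sd=0.0):
    """Noiseless (or near-noiseless) recordings driven by a 3-dim latent."""
    cfg = SyntheticConfig(n_subjects=1, duration_s=duration, carrier_amp=0.0)
    out = []
    for i in range(n_recs):
        st = StateSpec(f"c{i}", 100, noise_sd=noise_sd, ellipse_a=1.5)
        lat = generate_latent_trajectory(st, cfg.fs, cfg.duration_s, seed=i,
                                         jitter_sd=0.3, z_sd=0.3)
        cfg_i = SyntheticConfig(n_subjects=1, duration_s=duration,
                                carrier_amp=0.0, states=[st])
        out.append(embed_recording(lat, st, cfg_i, seed=i))
    return out


class TestInit:
    def test_seeded_initialization_is_deterministic(self):
        a = init_vae(19, 3, seed=5)
        b = init_vae(19, 3, seed=5)
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa, pb)

    def test_encoder_emits_mean_and_log_variance_heads(self):
        m = init_vae(19, 3)
        assert m.w_mu.shape == (32, 3) and m.w_lv.shape == (32, 3)

    def test_linear_architecture_accepted(self):
        m = init_vae(19, 2, hidden=())
        assert m.enc_layers == [] and m.w_mu.shape == (19, 2)
        assert len(m.dec_layers) == 1

    def test_invalid_latent_dimension(self):
        with pytest.raises(ValueError):
            init_vae(19, 0)


class TestEncode:
    def test_sigma_strictly_positive(self):
        m = init_vae(19, 4, seed=1)
        post = encode(m, np.random.default_rng(0).normal(size=(50, 19)))
        assert (post.sigma > 0).all()

    def test_duplicated_rows_give_duplicated_posteriors(self):
        m = init_vae(19, 4, seed=1)
        x = np.random.default_rng(1).normal(size=(1, 19))
        post = encode(m, np.vstack([x, x]))
        assert np.array_equal(post.mu[0], post.mu[1])

    def test_width_mismatch_and_nonfinite_rejected(self):
        m = init_vae(19, 4)
        with pytest.raises(ValueError):
            encode(m, np.zeros((2, 7)))
        bad = np.zeros((2, 19))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            encode(m, bad)


class TestReparameterize:
    def test_zero_sigma_limit_returns_mean(self):
        post = LatentPosterior(mu=np.ones((5, 2)), log_var=np.full((5, 2), -700.0))
        z = reparameterize(post, L=3, seed=0)
        assert np.array_equal(z, np.ones((3, 5, 2)))

    def test_sample_mean_matches_mu(self):
        mu = np.array([[1.0, -2.0, 0.5]])
        post = LatentPosterior(mu=mu, log_var=np.zeros((1, 3)))
        z = reparameterize(post, L=100_000, seed=1)
        se = 1.0 / np.sqrt(100_000)
        assert np.all(np.abs(z.mean(axis=0) - mu) < 3 * se)

    def test_seed_reproducible_and_L_validated(self):
        post = LatentPosterior(mu=np.zeros((2, 2)), log_var=np.zeros((2, 2)))
        assert np.array_equal(reparameterize(post, 5, seed=3),
                              reparameterize(post, 5, seed=3))
        with pytest.raises(ValueError):
            reparameterize(post, 0)


class TestKl:
    def test_standard_normal_posterior_has_zero_kl(self):
        post = LatentPosterior(mu=np.zeros((4, 6)), log_var=np.zeros((4, 6)))
        assert np.allclose(kl_gaussian(post), 0.0)

    def test_hand_computed_value(self):
        post = LatentPosterior(mu=np.array([[1.0]]), log_var=np.array([[0.0]]))
        assert kl_gaussian(post)[0] == pytest.approx(0.5, abs=1e-12)

    def test_matches_monte_carlo_estimate(self):
        rng = np.random.default_rng(7)
        mu = rng.normal(size=(1, 3))
        lv = rng.normal(scale=0.5, size=(1, 3))
        post = LatentPosterior(mu=mu, log_var=lv)
        sigma = np.exp(0.5 * lv)
        z = mu + sigma * rng.standard_normal((100_000, 3))
        log_q = -0.5 * (((z - mu) / sigma) ** 2 + LOG2PI + lv).sum(axis=1)
        log_p = -0.5 * (z ** 2 + LOG2PI).sum(axis=1)
        diff = log_q - log_p
        se = diff.std() / np.sqrt(diff.size)
        assert kl_gaussian(post)[0] == pytest.approx(diff.mean(), abs=3 * se)

    def test_nonnegative_for_random_posteriors(self):
        rng = np.random.default_rng(8)
        post = LatentPosterior(mu=rng.normal(size=(200, 4)),
                               log_var=rng.normal(size=(200, 4)))
        assert (kl_gaussian(post) >= 0).all()


class TestElbo:
    def test_zero_residual_zero_kl_gives_normalization_constant(self):
        # all-zero linear model on all-zero input: xhat = x = 0, mu=0, sigma=1
        m = init_vae(4, 2, hidden=())
        for p in m.parameters():
            p[:] = 0.0
        val = elbo(m, np.zeros((10, 4)), L=1, seed=0)
        assert val == pytest.approx(-0.5 * 4 * LOG2PI, abs=1e-12)

    def test_estimator_variance_shrinks_with_L(self):
        m = init_vae(6, 2, seed=2)
        x = np.random.default_rng(9).normal(size=(20, 6))
        small = [elbo(m, x, L=1, seed=s) for s in range(30)]
        large = [elbo(m, x, L=25, seed=s) for s in range(30)]
        assert np.var(large) < np.var(small)

    def test_elbo_below_reconstruction_term(self):
        m = init_vae(6, 2, seed=3)
        x = np.random.default_rng(10).normal(size=(40, 6))
        post = encode(m, x)
        z = reparameterize(post, L=1, seed=4)[0]
        xs = (x - m.x_mean) / m.x_std
        from aculatent.vae import _decode_std
        xhat, _ = _decode_std(m, z)
        recon = float(np.mean(-0.5 * np.sum((xs - xhat) ** 2 + LOG2PI, axis=1)))
        assert elbo(m, x, L=1, seed=4) <= recon + 1e-12

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            elbo(init_vae(4, 2), np.zeros((0, 4)))


class TestTraining:
    def test_loss_decreases_and_is_seed_reproducible(self):
        recs = rank3_recordings(duration=10.0, noise_sd=0.05)
        data = [r.data for r in recs]
        m1 = init_vae(19, 3, seed=4)
        m1, h1 = train(m1, data, n_epochs=3, optimizer="adam", stride=4, seed=4)
        m2 = init_vae(19, 3, seed=4)
        m2, h2 = train(m2, data, n_epochs=3, optimizer="adam", stride=4, seed=4)
        assert h1[-1] < h1[0]
        assert h1 == h2
        for pa, pb in zip(m1.parameters(), m2.parameters()):
            assert np.array_equal(pa, pb)

    def test_rank3_data_reconstructed_almost_perfectly_with_J3(self):
        recs = rank3_recordings(duration=30.0)
        data = [r.data for r in recs]
        m = init_vae(19, 3, seed=5)
        m, _ = train(m, data, n_epochs=12, optimizer="adam", stride=2, seed=5)
        assert reconstruction_performance(m, data) > 0.95

    def test_vae_close_to_optimal_linear_projection(self):
        """On 3-dim linear-Gaussian data a J=3 VAE comes within 0.05 of the
        optimal rank-3 linear projection's mean channel correlation."""
        recs = rank3_recordings(duration=30.0, noise_sd=0.05)
        data = [r.data for r in recs]
        x = np.concatenate([d for d in data], axis=1)  # channels x samples
        xc = x - x.mean(axis=1, keepdims=True)
        u, s, vt = np.linalg.svd(xc, full_matrices=False)
        proj = u[:, :3] @ u[:, :3].T @ xc
        pca_corr = np.mean([np.corrcoef(xc[c], proj[c])[0, 1] for c in range(19)])
        m = init_vae(19, 3, seed=6)
        m, _ = train(m, data, n_epochs=12, optimizer="adam", stride=2, seed=6)
        assert reconstruction_performance(m, data) > pca_corr - 0.05

    def test_divergence_raises_training_error(self):
        recs = rank3_recordings(duration=5.0)
        m = init_vae(19, 3, seed=7)
        with pytest.raises(TrainingError, match="pass"):
            train(m, [r.data for r in recs], n_epochs=2, learning_rate=1e12,
                  optimizer="sgd", stride=8, seed=7)

    def test_invalid_batch_size(self):
        with pytest.raises(ValueError):
            train(init_vae(4, 2), np.zeros((4, 100)), batch_size=0)


class TestReconstructionMetric:
    def test_identity_reconstruction_scores_one(self):
        m = linear_identity_model(4, decoder_sign=1.0)
        seg = np.random.default_rng(11).normal(size=(4, 200))
        assert reconstruction_performance(m, seg) == pytest.approx(1.0, abs=1e-12)

    def test_negated_reconstruction_scores_minus_one(self):
        m = linear_identity_model(4, decoder_sign=-1.0)
        seg = np.random.default_rng(12).normal(size=(4, 200))
        assert reconstruction_performance(m, seg) == pytest.approx(-1.0, abs=1e-12)

    def test_constant_channel_skipped_with_warning(self):
        m = linear_identity_model(3)
        seg = np.vstack([np.zeros(100),
                         np.random.default_rng(13).normal(size=(2, 100))])
        with pytest.warns(UserWarning, match="constant"):
            val = reconstruction_performance(m, seg)
        assert val == pytest.approx(1.0, abs=1e-12)


class TestLatentTrajectory:
    def test_coordinates_ordered_by_variance(self):
        m = init_vae(19, 3, seed=8)
        seg = np.random.default_rng(14).normal(size=(19, 500))
        traj = latent_trajectory(m, seg)
        v = traj.Z.var(axis=0)
        assert np.all(np.diff(v) <= 1e-15)
        assert traj.Z.shape == (500, 3)

    def test_excess_latents_carry_little_variance_on_rank3_data(self):
        recs = rank3_recordings(duration=30.0)
        data = [r.data for r in recs]
        m = init_vae(19, 5, seed=9)
        m, _ = train(m, data, n_epochs=12, optimizer="adam", stride=2, seed=9)
        traj = latent_trajectory(m, data[0])
        v = traj.Z.var(axis=0)
        assert v[3] <= 0.2 * v[2]
        assert v[4] <= 0.2 * v[2]

    def test_constant_segment_gives_stable_index_order(self):
        m = init_vae(19, 4, seed=10)
        traj = latent_trajectory(m, np.zeros((19, 50)))
        assert np.allclose(traj.Z.var(axis=0), 0.0)
        assert np.array_equal(traj.order, np.arange(4))

    def test_top3_requires_three_latents(self):
        m = init_vae(19, 2, seed=11)
        traj = latent_trajectory(m, np.zeros((19, 50)))
        with pytest.raises(ValueError):
            traj.top(3)
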