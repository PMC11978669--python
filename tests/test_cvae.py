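import numpy as np
import pytest

from hfodetect import cvae


def small_config(**kw):
    base = dict(latent_dim=8, epochs=5, batch_size=16, seed=0)
    base.update(kw)
    return cvae.CVAEConfig(**base)


class TestModelContracts:
    def test_decode_shape_and_range(self):
        model = cvae.build_model(small_config())
        out = model.decode(np.zeros(8))
        assert out.shape == (1, 64, 64)
        assert out.min() >= 0 and out.max() <= 1

    def test_same_seed_identical_parameters(self):
        a = cvae.build_model(small_config(seed=3))
        b = cvae.build_model(small_config(seed=3))
        np.testing.assert_array_equal(a.conv1.w, b.conv1.w)
        np.testing.assert_array_equal(a.fc_mu.w, b.fc_mu.w)

    def test_encoder_head_length_equals_latent_dim(self):
        model = cvae.build_model(small_config(latent_dim=13))
        mu, lv = model.encode(np.zeros((2, 64, 64)))
        assert mu.shape == (2, 13) and lv.shape == (2, 13)

    def test_invalid_latent_dim_rejected(self):
        with pytest.raises(ValueError):
            cvae.build_model(small_config(latent_dim=0))


class TestReparameterize:
    def test_zero_sigma_returns_mu(self):
        mu = np.array([1.0, -2.0, 0.5])
        z = cvae.reparameterize(mu, np.full(3, -40.0), noise_seed=0)
        np.testing.assert_allclose(z, mu, atol=1e-12)

    def test_monte_carlo_moments(self):
        z = cvae.reparameterize(np.zeros(10000), np.zeros(10000), noise_seed=1)
        assert abs(z.mean()) < 3.0 / np.sqrt(10000)
        assert abs(z.var() - 1.0) < 0.05

    def test_fixed_seed_reproducible(self):
        mu, ls = np.ones(5), np.zeros(5)
        np.testing.assert_array_equal(cvae.reparameterize(mu, ls, 7),
                                      cvae.reparameterize(mu, ls, 7))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cvae.reparameterize(np.zeros(3), np.zeros(4), 0)


class TestKL:
    def test_prior_has_zero_kl(self):
        np.testing.assert_allclose(cvae.gaussian_kl(np.zeros(5), np.zeros(5)), 0.0)

    def test_unit_mean_unit_sigma_is_half(self):
        np.testing.assert_allclose(cvae.gaussian_kl(np.ones(3), np.zeros(3)), 0.5)

    def test_closed_form_matches_monte_carlo(self):
        rng = np.random.default_rng(0)
        mu = rng.uniform(-2, 2, 4)
        log_sigma = rng.uniform(-1, 0.5, 4)
        n = 10 ** 5
        for m, ls in zip(mu, log_sigma):
            s = np.exp(ls)
            x = m + s * rng.standard_normal(n)
            # E_q[log q(x) - log p(x)]
            logq = -0.5 * ((x - m) / s) ** 2 - np.log(s)
            logp = -0.5 * x ** 2
            mc = np.mean(logq - logp)
            assert cvae.gaussian_kl(m, ls) == pytest.approx(mc, rel=0.02, abs=0.005)


class TestLoss:
    def test_pixels_outside_unit_interval_rejected(self):
        model = cvae.build_model(small_config())
        with pytest.raises(ValueError):
            cvae.elbo_loss(np.full((2, 64, 64), 1.5), model)

    def test_gradients_match_finite_differences(self):
        cfg = small_config(latent_dim=4, dtype="float64")
        model = cvae.build_model(cfg)
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, (2, 64, 64))
        eps = rng.standard_normal((2, 4))
        model.loss_and_grads(x, eps)
        for layer in (model.conv1, model.deconv2, model.fc_dec, model.fc_lv):
            grads = layer.dw
            flat = np.argsort(np.abs(grads), axis=None)[-3:]  # largest entries
            for fi in flat:
                idx = np.unravel_index(fi, layer.w.shape)
                h = 1e-6
                orig = layer.w[idx]
                layer.w[idx] = orig + h
                lp, _, _ = model.loss_and_grads(x, eps, want_grads=False)
                layer.w[idx] = orig - h
                lm, _, _ = model.loss_and_grads(x, eps, want_grads=False)
                layer.w[idx] = orig
                fd = (lp - lm) / (2 * h)
                assert grads[idx] == pytest.approx(fd, rel=1e-4, abs=1e-7)

    def test_perfect_reconstruction_limit(self):
        # cross-entropy of a binary target against probabilities -> target
        target = np.zeros((1, 64, 64))
        target[0, 10:20, 10:20] = 1.0
        for p, expect_small in [(0.5, False), (0.999, True)]:
            logits = np.where(target > 0.5, np.log(p / (1 - p)), -np.log(p / (1 - p)))
            bce = np.maximum(logits, 0) - logits * target + np.log1p(np.exp(-np.abs(logits)))
            if expect_small:
                assert bce.sum() < 10.0
            else:
                assert bce.sum() > 1000.0


class TestTraining:
    def test_loss_history_length_and_epoch_cap(self, two_class_images):
        imgs, _ = two_class_images
        _, hist = cvae.train(imgs, small_config(epochs=3))
        assert len(hist) == 3
        with pytest.raises(ValueError):
            cvae.train(imgs, small_config(epochs=201))

    def test_training_reduces_loss(self, two_class_images):
        imgs, _ = two_class_images
        _, hist = cvae.train(imgs, small_config(epochs=10))
        assert hist[-1] < hist[0]

    def test_empty_or_tiny_dataset_rejected(self):
        with pytest.raises(ValueError):
            cvae.train(np.zeros((0, 64, 64)), small_config())
        with pytest.raises(ValueError):
            cvae.train(np.zeros((8, 64, 64)), small_config(batch_size=16))

    def test_reconstruction_contract_and_untrained_guard(self, two_class_images):
        imgs, _ = two_class_images
        model, _ = cvae.train(imgs, small_config(epochs=5))
        recon = cvae.reconstruct(imgs[:10], model)
        assert recon.shape == (10, 64, 64)
        assert recon.min() >= 0 and recon.max() <= 1
        fresh = cvae.build_model(small_config())
        with pytest.raises(ValueError):
            cvae.reconstruct(imgs[:2], fresh)

    def test_within_class_distance_below_between_class(self, two_class_images):
        imgs, labels = two_class_images
        model, _ = cvae.train(imgs, small_config(epochs=15, latent_dim=8))
        recon = cvae.reconstruct(imgs, model)
        flat = recon.reshape(len(recon), -1)
        a, b = flat[labels == 0], flat[labels == 1]
        within = np.mean([np.linalg.norm(a - a.mean(0), axis=1).mean(),
                          np.linalg.norm(b - b.mean(0), axis=1).mean()])
        between = np.linalg.norm(a.mean(0) - b.mean(0))
        assert within < between

    def test_training_beats_untrained_on_held_out(self, two_class_images):
        imgs, _ = two_class_images
        train_set, held_out = imgs[:60], imgs[60:]
        cfg = small_config(epochs=15)
        model, _ = cvae.train(train_set, cfg)
        untrained = cvae.build_model(cfg)
        mse_trained = np.mean((cvae.reconstruct(held_out, model) - held_out) ** 2)
        mse_untrained = np.mean((cvae.reconstruct_raw(held_out, untrained) - held_out) ** 2)
        assert mse_trained < mse_untrained

    def test_save_load_roundtrip(self, two_class_images, tmp_path):
        imgs, _ = two_class_images
        model, _ = cvae.train(imgs, small_config(epochs=2))
        path = tmp_path / "model.npz"
        cvae.save_model(model, str(path))
        loaded = cvae.load_model(str(path))
        np.testing.assert_allclose(cvae.reconstruct(imgs[:4], loaded),
                                   cvae.reconstruct(imgs[:4], model))
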