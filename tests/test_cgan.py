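"""Conditional-GAN module: builders, losses, training and inference."""

import numpy as np
import pytest

from synct import nn
from synct.cgan import (
    CGANTranslator,
    DiscriminatorConfig,
    GeneratorConfig,
    TrainConfig,
    TrainedModel,
    build_discriminator,
    build_generator,
    count_parameters,
    discriminator_loss,
    generator_loss,
    infer_volume,
    small_discriminator_config,
    small_generator_config,
    train,
)
from synct.image_quality import mae

TINY_G = GeneratorConfig(layers_per_block=(1, 1, 1, 1, 1), bottleneck_layers=1,
                         growth_rate=4, initial_features=4, dropout_rate=0.0)
TINY_D = DiscriminatorConfig(base_features=4)


class TestBuilders:
    @pytest.mark.parametrize("shape", [(64, 64), (64, 96)])
    def test_generator_is_fully_convolutional(self, shape):
        g = build_generator(TINY_G, seed=0)
        x = nn.Tensor(np.zeros((1, 1, *shape), np.float32))
        out = g.eval()(x)
        assert out.data.shape == (1, 1, *shape)
        assert np.abs(out.data).max() <= 1.0  # bounded activation

    def test_indivisible_input_raises_actionable_error(self):
        g = build_generator(TINY_G, seed=0)
        with pytest.raises(ValueError, match="divisible by 32"):
            g(nn.Tensor(np.zeros((1, 1, 50, 64), np.float32)))

    def test_discriminator_patch_map_in_unit_interval(self, rng):
        d = build_discriminator(TINY_D, seed=0)
        x = nn.Tensor(rng.normal(size=(2, 2, 64, 64)).astype(np.float32))
        out = d(x)
        assert out.data.ndim == 4 and out.data.shape[2] > 1, \
            "patch discriminator must emit a map, not a scalar"
        assert out.data.min() >= 0.0 and out.data.max() <= 1.0

    def test_discriminator_rejects_single_channel(self):
        d = build_discriminator(TINY_D, seed=0)
        with pytest.raises(ValueError):
            d(nn.Tensor(np.zeros((1, 1, 64, 64), np.float32)))

    def test_zero_weights_give_half_everywhere(self, rng):
        d = build_discriminator(TINY_D, seed=0)
        for p in d.parameters():
            p.data[...] = 0.0
        d.eval()
        out = d(nn.Tensor(rng.normal(size=(1, 2, 64, 64)).astype(np.float32)))
        np.testing.assert_allclose(out.data, 0.5, atol=1e-6)

    def test_same_seed_builds_identical_networks(self):
        a = build_generator(TINY_G, seed=4)
        b = build_generator(TINY_G, seed=4)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)


class TestParameterCounts:
    def test_single_conv_with_bias(self):
        conv = nn.Conv2d(1, 8, 3, np.random.default_rng(0))
        assert count_parameters(conv) == 3 * 3 * 1 * 8 + 8 == 80

    def test_frozen_parameters_excluded(self):
        conv = nn.Conv2d(1, 8, 3, np.random.default_rng(0))
        conv.weight.requires_grad = False
        assert count_parameters(conv) == 8

    def test_default_generator_matches_calibrated_count(self):
        g = build_generator()
        assert round(count_parameters(g) / 1e6, 1) == 5.4

    def test_default_discriminator_matches_calibrated_count(self):
        d = build_discriminator()
        assert round(count_parameters(d) / 1e6, 1) == 1.6


class TestLosses:
    def test_equal_images_and_indifferent_critic(self):
        half = nn.Tensor(np.full((1, 1, 4, 4), 0.5, np.float32))
        z = nn.Tensor(np.zeros((1, 1, 8, 8), np.float32))
        total, comp = generator_loss(half, z, z, 100.0)
        assert float(total.data) == pytest.approx(-np.log(0.5), abs=1e-5)
        assert comp["l1"] == 0.0

    def test_constant_offset_adds_lambda_times_mae(self):
        half = nn.Tensor(np.full((1, 1, 4, 4), 0.5, np.float32))
        z = nn.Tensor(np.zeros((1, 1, 8, 8), np.float32))
        p = nn.Tensor(np.full((1, 1, 8, 8), 0.1, np.float32))
        total, _ = generator_loss(half, p, z, 100.0)
        assert float(total.data) == pytest.approx(-np.log(0.5) + 10.0, abs=1e-4)

    def test_lambda_zero_isolates_adversarial_term(self, rng):
        d = nn.Tensor(rng.uniform(0.1, 0.9, (1, 1, 4, 4)).astype(np.float32))
        p = nn.Tensor(rng.normal(size=(1, 1, 8, 8)).astype(np.float32))
        t = nn.Tensor(rng.normal(size=(1, 1, 8, 8)).astype(np.float32))
        total, comp = generator_loss(d, p, t, 0.0)
        assert float(total.data) == pytest.approx(comp["adversarial"], abs=1e-6)

    def test_decomposition_matches_image_quality_mae(self, rng):
        """generator_loss == adversarial + lambda * MAE with the stage-1
        MAE on the same tensors, exactly."""
        for _ in range(10):
            d = nn.Tensor(rng.uniform(0.05, 0.95, (2, 1, 4, 4)).astype(np.float32))
            p = nn.Tensor(rng.normal(size=(2, 1, 16, 16)).astype(np.float32))
            t = nn.Tensor(rng.normal(size=(2, 1, 16, 16)).astype(np.float32))
            lam = float(rng.uniform(0, 200))
            total, comp = generator_loss(d, p, t, lam)
            assert comp["l1"] == pytest.approx(mae(p.data, t.data), rel=1e-6)
            assert float(total.data) == pytest.approx(
                comp["adversarial"] + lam * comp["l1"], rel=1e-5)

    def test_discriminator_closed_forms(self):
        half = nn.Tensor(np.full((1, 1, 4, 4), 0.5, np.float32))
        assert float(discriminator_loss(half, half).data) == \
            pytest.approx(-2 * np.log(0.5), abs=1e-5)
        eps = 1e-4
        good_r = nn.Tensor(np.full((1, 1, 4, 4), 1 - eps, np.float32))
        good_f = nn.Tensor(np.full((1, 1, 4, 4), eps, np.float32))
        assert float(discriminator_loss(good_r, good_f).data) < 1e-3
        assert float(discriminator_loss(good_f, good_r).data) > 2.0


class TestTraining:
    def _toy_data(self, rng, n=8, size=32):
        x = rng.normal(scale=0.2, size=(n, size, size)).astype(np.float32)
        return x

    def test_identity_task_converges_close_to_input(self, noiseless_sample):
        """Trained on pairs with target == input (noiseless anatomy
        slices), the translated output stays within 5 HU of the input."""
        from synct.pipeline import training_slices
        from synct.preprocess import PreprocessConfig

        pp = PreprocessConfig(roi_size=(32, 32, 150), train_crop=None)
        X, _ = training_slices([noiseless_sample], pp)
        est = CGANTranslator(epochs=100, batch_size=4, lr_g=2e-3,
                             adam_betas=(0.9, 0.999), seed=0)
        est.fit(X, X, validation_data=(X[:2], X[:2]))
        pred = est.predict(X[:4])
        hu_err = np.abs(pred - X[:4]).mean() * 325.0  # [-1,1] -> 650 HU
        assert hu_err < 5.0

    def test_seeded_runs_reproduce_loss_curves(self, rng):
        X = self._toy_data(rng, n=4)
        hists = []
        for _ in range(2):
            est = CGANTranslator(epochs=2, batch_size=2, seed=9)
            est.fit(X, X, validation_data=(X[:1], X[:1]))
            hists.append(est.history_)
        assert hists[0]["g_loss"] == hists[1]["g_loss"]
        assert hists[0]["val_l1"] == hists[1]["val_l1"]

    def test_empty_dataset_rejected(self):
        est = CGANTranslator(epochs=1)
        with pytest.raises(ValueError):
            est.fit(np.zeros((0, 32, 32)), np.zeros((0, 32, 32)))

    def test_predict_before_fit_raises(self):
        with pytest.raises(RuntimeError):
            CGANTranslator().predict(np.zeros((1, 32, 32)))

    def test_sklearn_params_round_trip(self):
        est = CGANTranslator(lambda_l1=50.0, epochs=3)
        params = est.get_params()
        assert params["lambda_l1"] == 50.0
        est.set_params(epochs=7)
        assert est.epochs == 7


class TestInference:
    @pytest.fixture(scope="class")
    def identity_model(self):
        rng = np.random.default_rng(1)
        X = rng.normal(scale=0.2, size=(8, 32, 32)).astype(np.float32)
        cfg = TrainConfig(epochs=10, lr_g=2e-3, adam_betas=(0.9, 0.999),
                          train_crop=None, seed=1)
        return train((X, X), (X[:2], X[:2]),
                     small_generator_config(), small_discriminator_config(),
                     cfg)

    def test_outside_roi_bit_identical_to_input(self, identity_model,
                                                default_sample):
        from synct.preprocess import PreprocessConfig

        pp = PreprocessConfig(roi_size=(32, 32, 16), train_crop=None)
        nct = default_sample.pair.nct
        out = infer_volume(identity_model, nct, pp,
                           heart_mask=default_sample.structures["heart"])
        changed = out.voxels != nct.voxels
        assert changed.sum() <= 32 * 32 * 16
        idx = np.argwhere(changed)
        for a in range(3):
            assert idx[:, a].max() - idx[:, a].min() < (32, 32, 16)[a]

    def test_inference_is_deterministic(self, identity_model, default_sample):
        from synct.preprocess import PreprocessConfig

        pp = PreprocessConfig(roi_size=(32, 32, 16), train_crop=None)
        a = infer_volume(identity_model, default_sample.pair.nct, pp)
        b = infer_volume(identity_model, default_sample.pair.nct, pp)
        np.testing.assert_array_equal(a.voxels, b.voxels)

    def test_save_load_round_trip(self, identity_model, tmp_path, rng):
        prefix = str(tmp_path / "ckpt")
        identity_model.save(prefix)
        loaded = TrainedModel.load(prefix)
        X = rng.normal(scale=0.2, size=(2, 32, 32)).astype(np.float32)
        np.testing.assert_array_equal(identity_model.estimator.predict(X),
                                      loaded.estimator.predict(X))
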