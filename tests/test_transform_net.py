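"""Transform block: architecture contract, loss, training behavior."""

import numpy as np
import pytest

from mrsinet import transform_net as T
from mrsinet.errors import (ConfigurationError, DataError, DivergenceError,
                            InvalidArgumentError)
from mrsinet.records import SplitArrays


class TestConfig:
    def test_defaults_match_reference_hyperparameters(self):
        cfg = T.TransformNetConfig()
        assert cfg.learning_rate == 5e-6
        assert cfg.batch_size == 20
        assert cfg.epochs == 200
        assert cfg.loss == "mse"
        assert len(cfg.fc_widths) == 3
        assert len(cfg.conv_channels) == 2

    @pytest.mark.parametrize("kwargs", [
        {"fc_widths": (1024, 1024)},
        {"conv_channels": (64,)},
        {"conv_kernel": 4},
        {"fc_widths": (512, 512, 512)},  # last width must be n_points
        {"loss": "mae"},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            T.TransformNetConfig(**kwargs)


class TestBuild:
    def test_layer_type_sequence(self):
        model = T.build_transform_net(seed=0)
        assert model.layer_types() == ["FC", "FC", "FC", "Conv", "Conv",
                                       "Deconv"]

    def test_output_shape_contract(self):
        cfg = T.TransformNetConfig(fc_widths=(64, 64, 128), n_points=128,
                                   conv_channels=(4, 4))
        model = T.build_transform_net(cfg, seed=0)
        x = np.random.default_rng(0).normal(size=(5, 128, 2)).astype(np.float32)
        out = T.transform(model, x)
        assert out.shape == (5, 128, 2)
        assert np.all(np.isfinite(out))

    def test_same_seed_identical_parameters(self):
        a = T.build_transform_net(seed=3)
        b = T.build_transform_net(seed=3)
        for (_, x, _), (_, y, _) in zip(a.named_state(), b.named_state()):
            np.testing.assert_array_equal(x, y)
        c = T.build_transform_net(seed=4)
        assert any(not np.array_equal(x, y) for (_, x, _), (_, y, _)
                   in zip(a.named_state(), c.named_state()))

    def test_parameter_count_reported(self):
        model = T.build_transform_net(seed=0)
        assert model.n_parameters() > 1_000_000


class TestMseLoss:
    def test_exact_prediction_is_zero(self):
        y = np.random.default_rng(1).uniform(size=(3, 1024, 2))
        assert T.mse_loss(y, y.copy()) == 0.0

    def test_constant_offset(self):
        assert T.mse_loss(np.zeros((2, 8, 2)), np.ones((2, 8, 2))) == 1.0

    def test_hand_example(self):
        assert T.mse_loss(np.array([0.0, 1.0]),
                          np.array([0.5, 0.5])) == pytest.approx(0.25)

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=(4, 100, 2))
        y_hat = rng.normal(size=(4, 100, 2))
        oracle = float(sum((a - b) ** 2 for a, b in
                           zip(y.ravel(), y_hat.ravel())) / y.size)
        assert T.mse_loss(y, y_hat) == pytest.approx(oracle, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            T.mse_loss(np.zeros((2, 8)), np.zeros((3, 8)))


def _tiny_split(n, rng, n_points=128):
    fids = rng.normal(size=(n, n_points, 2)).astype(np.float32)
    targets = rng.uniform(size=(n, n_points, 2)).astype(np.float32)
    return SplitArrays(fids=fids, targets=targets,
                       ppm_axis=np.linspace(-3, 12, n_points))


class TestTraining:
    def test_empty_split_rejected(self):
        cfg = T.TransformNetConfig(fc_widths=(32, 32, 128), n_points=128,
                                   conv_channels=(2, 2), epochs=1)
        model = T.build_transform_net(cfg, seed=0)
        rng = np.random.default_rng(0)
        empty = _tiny_split(0, rng)
        with pytest.raises(DataError):
            T.train_transform(model, empty, _tiny_split(4, rng), cfg)

    def test_same_seed_same_history(self):
        rng = np.random.default_rng(3)
        train, val = _tiny_split(32, rng), _tiny_split(8, rng)
        cfg = T.TransformNetConfig(fc_widths=(32, 32, 128), n_points=128,
                                   conv_channels=(2, 2), epochs=2,
                                   learning_rate=1e-3, batch_size=8)
        h1 = T.train_transform(T.build_transform_net(cfg, seed=1), train, val,
                               cfg, seed=5)[1]
        h2 = T.train_transform(T.build_transform_net(cfg, seed=1), train, val,
                               cfg, seed=5)[1]
        assert h1.train_loss == h2.train_loss
        assert h1.val_loss == h2.val_loss


class TestTinyNoiselessTraining:
    def test_validation_improves(self, tiny_noiseless_transform):
        _, _, history = tiny_noiseless_transform
        assert history.val_loss[-1] < history.val_loss[0]

    def test_loss_curve_non_increasing_after_smoothing(self,
                                                       tiny_noiseless_transform):
        """5-epoch-window smoothed training loss must not increase
        (guards against a mis-set learning rate)."""
        _, _, history = tiny_noiseless_transform
        smooth = np.convolve(history.train_loss, np.ones(5) / 5, mode="valid")
        assert np.all(np.diff(smooth) <= 1e-5)

    def test_batch_invariance(self, tiny_noiseless_transform):
        model, ds, _ = tiny_noiseless_transform
        single = T.transform(model, ds.test.fids[:1])
        batch = T.transform(model, ds.test.fids[:16])
        np.testing.assert_allclose(single[0], batch[0], atol=1e-4)

    def test_wrong_input_length_rejected(self, tiny_noiseless_transform):
        model, _, _ = tiny_noiseless_transform
        with pytest.raises(InvalidArgumentError):
            T.transform(model, np.zeros((1, 512, 2), dtype=np.float32))

class TestTrainedAtDeskScale:
    """Properties of the session's desk-scale trained transform model."""

    def test_predictions_beat_mean_spectrum_predictor(self, paired_dataset,
                                                      trained_transform):
        """The model is input-specific: it outperforms always predicting
        the training-set mean target spectrum."""
        model, _, _ = trained_transform
        pred = T.transform(model, paired_dataset.test.fids)
        model_mse = T.mse_loss(paired_dataset.test.targets, pred)
        mean_target = paired_dataset.train.targets.mean(axis=0,
                                                        keepdims=True)
        mean_mse = T.mse_loss(
            paired_dataset.test.targets,
            np.broadcast_to(mean_target, paired_dataset.test.targets.shape))
        assert model_mse < mean_mse

    def test_denoising_beats_noisy_dft_baseline(self, trained_transform):
        """At sigma >= 0.5, the trained net reconstructs better than the
        min-max-normalized DFT of the noisy input (denoising adds value)."""
        import mrsinet as M
        from mrsinet.simulate import AugmentParams
        model, _, _ = trained_transform
        aug = AugmentParams(noise_range=(0.5, 1.0))
        ds = M.generate_dataset(200, aug=aug, master_seed=424242,
                                split_fractions=(1.0, 0.0, 0.0))
        pred = T.transform(model, ds.train.fids)
        model_mse = T.mse_loss(ds.train.targets, pred)
        fids = ds.train.fids[..., 0] + 1j * ds.train.fids[..., 1]
        spec = np.fft.fftshift(np.fft.fft(fids, axis=1), axes=1)
        ch = np.stack([spec.real, spec.imag], axis=-1)
        lo = ch.min(axis=1, keepdims=True)
        hi = ch.max(axis=1, keepdims=True)
        baseline = (ch - lo) / (hi - lo)
        baseline_mse = T.mse_loss(ds.train.targets, baseline)
        assert model_mse < baseline_mse
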