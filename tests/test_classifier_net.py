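"""Classifier block: BCE, dense connectivity, freezing, training guards."""

import numpy as np
import pytest

from mrsinet import classifier_net as C
from mrsinet import transform_net as T
from mrsinet.errors import (ConfigurationError, DataError,
                            InvalidArgumentError)
from mrsinet.nn import autograd as ag
from mrsinet.records import SplitArrays


def bce_oracle(labels, probs, eps=1e-7):
    total = 0.0
    for y, p in zip(labels, probs):
        p = min(max(p, eps), 1 - eps)
        total += -(y * np.log(p) + (1 - y) * np.log(1 - p))
    return total / len(labels)


class TestBceLoss:
    def test_near_perfect_prediction_near_zero(self):
        assert C.bce_loss(np.array([1.0]), np.array([1.0 - 1e-7])) < 1e-6

    def test_coin_flip_is_ln_two(self):
        assert C.bce_loss(np.array([1, 0]), np.array([0.5, 0.5])) == \
            pytest.approx(np.log(2), rel=1e-9)

    def test_hand_example_quarter(self):
        assert C.bce_loss(np.array([1.0]), np.array([0.25])) == \
            pytest.approx(-np.log(0.25), rel=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_oracle_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, 64).astype(float)
        probs = rng.uniform(size=64)
        assert C.bce_loss(labels, probs) == \
            pytest.approx(bce_oracle(labels, probs), abs=1e-9)

    def test_nonbinary_labels_rejected(self):
        with pytest.raises(InvalidArgumentError):
            C.bce_loss(np.array([0.5]), np.array([0.5]))


def _small_transform_cfg(n_points=128):
    return T.TransformNetConfig(n_points=n_points,
                                fc_widths=(32, 32, n_points),
                                conv_channels=(2, 2), epochs=1)


def _small_classifier_cfg(**overrides):
    base = dict(dense_blocks=2, layers_per_block=2, growth_rate=4,
                init_channels=8, learning_rate=1e-3, batch_size=16, epochs=2)
    base.update(overrides)
    return C.ClassifierConfig(**base)


def _combined(seed=0, **clf_overrides):
    transform = T.build_transform_net(_small_transform_cfg(), seed=seed)
    return C.build_combined(transform, _small_classifier_cfg(**clf_overrides),
                            seed=seed)


def _labeled_split(n, rng, n_points=128, balanced=True):
    fids = rng.normal(size=(n, n_points, 2)).astype(np.float32)
    labels = np.arange(n) % 2 if balanced else np.zeros(n, dtype=int)
    return SplitArrays(fids=fids, targets=np.zeros_like(fids),
                       ppm_axis=np.linspace(-3, 12, n_points),
                       labels=np.asarray(labels, dtype=np.int8))


class TestArchitecture:
    def test_defaults_match_reference_hyperparameters(self):
        cfg = C.ClassifierConfig()
        assert cfg.learning_rate == 5e-5
        assert cfg.batch_size == 200
        assert cfg.epochs == 100
        assert cfg.loss == "bce" and cfg.head == "sigmoid"

    def test_dense_connectivity_channel_growth(self):
        """Layer l of a dense block sees init + l*growth input channels."""
        cfg = _small_classifier_cfg()
        model = _combined().classifier
        ch = cfg.init_channels
        for b in range(cfg.dense_blocks):
            for l in range(cfg.layers_per_block):
                layer = getattr(model, f"block{b}_layer{l}")
                assert layer.conv.weight.shape[1] == ch + l * cfg.growth_rate
            ch = (ch + cfg.layers_per_block * cfg.growth_rate)
            if b < cfg.dense_blocks - 1:
                ch = ch // 2

    def test_output_is_probability(self):
        model = _combined()
        rng = np.random.default_rng(0)
        probs = C.predict(model, rng.normal(size=(9, 128, 2)).astype(np.float32))
        assert probs.shape == (9,)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_batch_invariance(self):
        model = _combined()
        x = np.random.default_rng(1).normal(size=(8, 128, 2)).astype(np.float32)
        one = C.predict(model, x[:1])
        full = C.predict(model, x)
        assert one[0] == pytest.approx(full[0], abs=1e-5)

    def test_checkpoint_shape_mismatch_rejected(self):
        transform = T.build_transform_net(_small_transform_cfg(), seed=0)
        bad_state = {k: v for k, v in transform.state_dict().items()
                     if "fc1" not in k}
        with pytest.raises(ConfigurationError):
            C.build_combined(bad_state, _small_classifier_cfg(),
                             transform_config=_small_transform_cfg())


class TestTrainingGuards:
    def test_single_class_rejected(self):
        rng = np.random.default_rng(2)
        model = _combined()
        split = _labeled_split(20, rng, balanced=False)
        with pytest.raises(DataError):
            C.train_classifier(model, split, split, model.config)

    def test_imbalanced_split_rejected_unless_allowed(self):
        rng = np.random.default_rng(3)
        model = _combined()
        split = _labeled_split(20, rng)
        split.labels = np.asarray([1] * 15 + [0] * 5, dtype=np.int8)
        with pytest.raises(DataError):
            C.train_classifier(model, split, split, model.config)
        cfg = _small_classifier_cfg(allow_imbalance=True, epochs=1)
        model2 = _combined(allow_imbalance=True, epochs=1)
        C.train_classifier(model2, split, split, cfg)  # no raise

    def test_unlabeled_split_rejected(self):
        rng = np.random.default_rng(4)
        model = _combined()
        split = _labeled_split(20, rng)
        split.labels = None
        with pytest.raises(DataError):
            C.train_classifier(model, split, split, model.config)


class TestFreezingContract:
    @pytest.mark.parametrize("fine_tune", [False, True])
    def test_transform_weights_frozen_or_updated(self, fine_tune):
        rng = np.random.default_rng(5)
        model = _combined(fine_tune_transform=fine_tune, epochs=2)
        before = {k: v.copy() for k, v in model.transform.state_dict().items()}
        train = _labeled_split(32, rng)
        val = _labeled_split(8, rng)
        C.train_classifier(model, train, val, model.config, seed=0)
        after = model.transform.state_dict()
        identical = all(np.array_equal(before[k], after[k]) for k in before)
        assert identical == (not fine_tune)

    def test_same_seed_same_history(self):
        rng = np.random.default_rng(6)
        train, val = _labeled_split(32, rng), _labeled_split(8, rng)
        h1 = C.train_classifier(_combined(), train, val, seed=9)[1]
        h2 = C.train_classifier(_combined(), train, val, seed=9)[1]
        assert h1.train_loss == h2.train_loss
        assert h1.val_loss == h2.val_loss


class TestOnSeparableTask:
    def test_glioma_scores_exceed_healthy_scores(self, trained_classifier,
                                                 labeled_dataset):
        model, _, _ = trained_classifier
        test = labeled_dataset.test
        probs = C.predict(model, test.fids)
        glioma = test.labels == 1
        assert probs[glioma].mean() > probs[~glioma].mean()

    def test_gradient_flows_end_to_end_when_fine_tuning(self,
                                                        trained_classifier):
        model, _, _ = trained_classifier
        x = np.random.default_rng(7).normal(
            size=(2, 1024, 2)).astype(np.float32)
        model.train()
        logits = model(ag.Tensor(x))
        model.zero_grad()
        loss = ag.bce_with_logits_loss(logits, np.array([1.0, 0.0]))
        loss.backward()
        t_grads = [p.grad for p in model.transform.parameters()]
        assert all(g is not None for g in t_grads)
        assert any(np.abs(g).max() > 0 for g in t_grads)
        model.eval()
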