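"""CNN protocol: preprocessing, augmentation, splits, training, CAM."""

import numpy as np
import pytest

from abequant import PhantomConfig, generate_cohort
from abequant.cnn import (
    DivergenceError,
    TrainConfig,
    augment,
    build_backbone,
    class_activation_map,
    make_splits,
    preprocess_slice,
    select_training_slices,
    train_eval,
    train_model,
    _encode,
    _to_batch,
)
from abequant.errors import ConfigurationError, DegenerateInputError


class _ForcedRng:
    """Deterministic RNG stub forcing the identity augmentation draw."""

    def uniform(self, low, high, size=None):
        if size is None:
            return 1.0 if (low, high) == (0.9, 1.1) else 0.0
        return np.zeros(size)

    def random(self):
        return 0.99  # never below the flip probability


class _SpyRng:
    """Delegating RNG that records every draw augment makes."""

    def __init__(self, seed):
        self._rng = np.random.default_rng(seed)
        self.uniform_draws = []
        self.random_draws = []

    def uniform(self, low, high, size=None):
        v = self._rng.uniform(low, high, size)
        self.uniform_draws.append(((low, high), v))
        return v

    def random(self):
        v = self._rng.random()
        self.random_draws.append(v)
        return v


def _slice_images(config, train_config):
    records, stacks = generate_cohort(config)
    images, labels, subjects = [], [], []
    for r in records:
        for s in select_training_slices(stacks[r.subject_id]):
            images.append(preprocess_slice(s.intensity, train_config.input_size))
            labels.append(r.group)
            subjects.append(r.subject_id)
    return images, labels, subjects


class TestPreprocess:
    def test_range_shape_and_channel_replication(self, rng):
        out = preprocess_slice(rng.normal(50, 10, size=(96, 96)), size=64)
        assert out.shape == (64, 64, 3)
        assert out.min() == pytest.approx(0.0) and out.max() == pytest.approx(1.0)
        assert np.array_equal(out[:, :, 0], out[:, :, 1])
        assert np.array_equal(out[:, :, 0], out[:, :, 2])

    def test_default_resizes_to_224(self, rng):
        out = preprocess_slice(rng.normal(size=(40, 40)))
        assert out.shape == (224, 224, 3)

    def test_constant_slice_rejected(self):
        with pytest.raises(DegenerateInputError):
            preprocess_slice(np.full((32, 32), 5.0))


class TestAugment:
    def test_forced_identity_draw(self, rng):
        image = preprocess_slice(rng.normal(size=(32, 32)), size=32)
        out = augment(image, _ForcedRng(), TrainConfig(input_size=32))
        assert out == pytest.approx(image, abs=1e-9)

    def test_fixed_seed_is_bit_identical(self, rng):
        image = preprocess_slice(rng.normal(size=(24, 24)), size=24)
        cfg = TrainConfig(input_size=24)
        a = augment(image, np.random.default_rng(5), cfg)
        b = augment(image, np.random.default_rng(5), cfg)
        assert np.array_equal(a, b)

    def test_draw_ranges_and_flip_frequency(self):
        """10^4 augmentation draws: flip frequency 0.5 +/- 0.02 and rotation
        angles inside the configured +/-30 degree range."""
        cfg = TrainConfig(input_size=8)
        spy = _SpyRng(0)
        tiny = np.zeros((4, 4))
        tiny[0, 0] = 1.0
        for _ in range(10_000):
            augment(tiny, spy, cfg)
        flips = np.mean([v < cfg.flip_probability for v in spy.random_draws])
        assert flips == pytest.approx(0.5, abs=0.02)
        # rotation draws are the scalar (-30, 30) draws; translation draws the
        # same range but as a length-2 vector
        angles = [v for (lo, hi), v in spy.uniform_draws
                  if (lo, hi) == (-30.0, 30.0) and np.ndim(v) == 0]
        assert len(angles) == 10_000
        assert -30 <= min(angles) and max(angles) <= 30

    def test_shape_and_label_preserved(self, rng):
        image = preprocess_slice(rng.normal(size=(32, 32)), size=32)
        out = augment(image, np.random.default_rng(0), TrainConfig(input_size=32))
        assert out.shape == image.shape


class TestMakeSplits:
    def test_80_20_arithmetic_on_190_slices(self):
        labels = np.array(["ABE"] * 95 + ["non-ABE"] * 95)
        ids = np.arange(190).astype(str)
        cfg = TrainConfig(split_unit="slice", seed=0)
        plan = make_splits(ids, labels, cfg)
        assert len(plan.train_idx) == 152 and len(plan.test_idx) == 38
        assert len(plan.folds) == 5

    def test_subject_unit_leakage_guard(self):
        subjects = np.repeat([f"S{i}" for i in range(20)], 3)
        labels = np.repeat(["ABE"] * 10 + ["non-ABE"] * 10, 3)
        plan = make_splits(subjects, labels, TrainConfig(split_unit="subject", seed=1))
        train_subj = set(subjects[plan.train_idx])
        test_subj = set(subjects[plan.test_idx])
        assert not train_subj & test_subj
        for tr, va in plan.folds:
            assert not set(subjects[tr]) & set(subjects[va])

    def test_same_seed_identical_partitions(self):
        labels = np.array(["ABE"] * 30 + ["non-ABE"] * 30)
        ids = np.arange(60).astype(str)
        cfg = TrainConfig(split_unit="slice", seed=7)
        a, b = make_splits(ids, labels, cfg), make_splits(ids, labels, cfg)
        assert np.array_equal(a.train_idx, b.train_idx)
        assert np.array_equal(a.test_idx, b.test_idx)

    def test_class_smaller_than_folds_rejected(self):
        labels = np.array(["ABE"] * 3 + ["non-ABE"] * 30)
        with pytest.raises(ConfigurationError):
            make_splits(np.arange(33).astype(str), labels,
                        TrainConfig(split_unit="slice", folds=5))


class TestTraining:
    def test_separable_phantoms_reach_high_cv_accuracy(self):
        """Widely separated group ratios should be nearly perfectly learnable:
        five folds, mean cross-validated accuracy above 90%."""
        ph = PhantomConfig(n_pos=15, n_neg=15, seed=3, noise_cv=0.01, n_slices=5,
                          slice_shape=(96, 96))
        ph.ratio_params["ABE"] = {"GP": (1.6, 0.03), "STN": (1.8, 0.03)}
        ph.ratio_params["non-ABE"] = {"GP": (0.6, 0.03), "STN": (1.8, 0.03)}
        tc = TrainConfig(input_size=32, learning_rate=0.01, max_epochs=20,
                         minibatch=10, folds=5, base_channels=8, n_stages=2,
                         translation_pixels=(-3, 3), rotation_degrees=(-15, 15),
                         seed=0)
        images, labels, subjects = _slice_images(ph, tc)
        result = train_eval(images, labels, subjects, tc, final_eval=False)
        assert len(result.fold_metrics) == 5
        accs = [ms.accuracy for ms in result.fold_metrics]
        assert np.mean(accs) > 90.0
        # history is per-iteration and matches the training schedule
        for (tr, _), hist in zip(result.split.folds, result.histories):
            iters = tc.max_epochs * int(np.ceil(len(tr) / tc.minibatch))
            assert len(hist["loss"]) == len(hist["accuracy"]) == iters

    def test_divergence_raises_with_history(self, rng):
        images = [preprocess_slice(rng.normal(size=(24, 24)), size=16)
                  for _ in range(8)]
        y = np.array([0, 1] * 4)
        tc = TrainConfig(input_size=16, learning_rate=1e200, max_epochs=3,
                         minibatch=4, augment=False, seed=0)
        model = build_backbone(tc, seed=0)
        with pytest.raises(DivergenceError) as err:
            train_model(model, images, y, tc, np.random.default_rng(0))
        assert isinstance(err.value.history["loss"], list)


class TestClassActivationMap:
    def _tiny_model(self, rng, size=16):
        tc = TrainConfig(input_size=size, base_channels=4, n_stages=2, seed=0)
        model = build_backbone(tc, seed=0)
        image = preprocess_slice(rng.normal(size=(size, size)), size=size)
        return model, image

    def test_shape_and_range(self, rng):
        model, image = self._tiny_model(rng)
        heat = class_activation_map(model, image)
        assert heat.shape == image.shape[:2]
        assert heat.min() >= 0.0 and heat.max() <= 1.0

    def test_uniform_head_weights_give_constant_map(self, rng):
        model, image = self._tiny_model(rng)
        model.fc_weight[...] = 0.0
        heat = class_activation_map(model, image)
        assert np.all(heat == heat.flat[0])

    def test_requires_preprocessed_image(self, rng):
        model, _ = self._tiny_model(rng)
        with pytest.raises(ValueError):
            class_activation_map(model, rng.normal(size=(16, 16)))
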