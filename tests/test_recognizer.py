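"""Recognizer tests: contracts, shift equivariance, training behavior.

Heavy checks (learning on the default architecture) live in the acceptance
suite; here the training machinery is exercised with a small architecture
and short synthetic datasets.
"""

from __future__ import annotations

import numpy as np
import pytest

from broilervox.calls import CallType, RASTER_CLASSES
from broilervox.frontend import LogMelSpectrogram
from broilervox.recognizer import (
    LabeledDataset,
    RecognizerConfig,
    TrainingConfig,
    build_model,
    evaluate,
    infer,
    load_model,
    save_model,
    synthesize_training_set,
    train,
)
from conftest import tiny_config


@pytest.fixture(scope="module")
def default_model():
    return build_model(RecognizerConfig(seed=3))


def random_spec(n_frames: int, seed: int = 0) -> LogMelSpectrogram:
    rng = np.random.default_rng(seed)
    return LogMelSpectrogram(rng.normal(-5.0, 3.0, size=(n_frames, 64)))


class TestBuildContracts:
    def test_default_parameter_count_within_band(self, default_model):
        assert 960_000 <= default_model.parameter_count() <= 1_440_000

    def test_eleven_conv2d_plus_one_conv1d(self):
        cfg = RecognizerConfig()
        assert cfg.n_conv2d_layers == 11
        assert cfg.temporal_downsample_factor == 24

    def test_undersized_config_rejected_with_count(self):
        cfg = RecognizerConfig(channels=((8,), (8,), (8,), (8,)))
        with pytest.raises(ValueError, match=r"parameter count \d+"):
            build_model(cfg)

    def test_bad_stride_plan_rejected(self):
        cfg = RecognizerConfig(strides=((2, 2), (2, 2), (2, 2), (2, 2)))
        with pytest.raises(ValueError, match="24"):
            build_model(cfg)


class TestInfer:
    def test_6000_frames_give_250_steps(self, default_model):
        raster = infer(default_model, random_spec(6000))
        assert raster.n_steps == 250
        assert raster.frame_duration == 0.24

    def test_6024_frames_give_251_steps(self, default_model):
        assert infer(default_model, random_spec(6024)).n_steps == 251

    def test_partial_step_frames_are_cropped(self, default_model):
        assert infer(default_model, random_spec(6010)).n_steps == 250

    def test_rows_sum_to_one(self, default_model):
        for seed in range(10):
            r = infer(default_model, random_spec(48, seed))
            assert np.all(np.abs(r.scores.sum(axis=1) - 1.0) <= 1e-5)
            assert np.all((r.scores >= 0) & (r.scores <= 1))

    def test_too_short_input_yields_empty_raster(self, default_model):
        r = infer(default_model, random_spec(23))
        assert r.n_steps == 0 and r.scores.shape == (0, 6)

    def test_age_estimate_positive(self, default_model):
        r = infer(default_model, random_spec(96))
        assert np.all(r.age_estimate >= 0)

    def test_inference_is_deterministic(self, default_model):
        s = random_spec(240, 5)
        assert np.array_equal(infer(default_model, s).scores, infer(default_model, s).scores)

    def test_shift_by_one_step_shifts_raster(self, default_model):
        """Delaying the input by 24 frames shifts the raster by one row,
        away from receptive-field edges."""
        spec = random_spec(360, 7)
        full = infer(default_model, spec).scores
        sub = infer(default_model, LogMelSpectrogram(spec.values[24:])).scores
        edge = 6
        assert np.allclose(full[1 + edge : sub.shape[0] - edge], sub[edge : -edge - 1], atol=1e-3)

    def test_concatenation_consistency(self, default_model):
        """infer(A||B) agrees with infer(A), infer(B) away from the seam."""
        a, b = random_spec(240, 8), random_spec(240, 9)
        joint = infer(default_model, LogMelSpectrogram(np.vstack([a.values, b.values]))).scores
        ra = infer(default_model, a).scores
        rb = infer(default_model, b).scores
        edge = 6
        assert np.allclose(joint[edge : 10 - edge], ra[edge : 10 - edge], atol=1e-3)
        assert np.allclose(joint[10 + edge : 20 - edge], rb[edge : 10 - edge], atol=1e-3)


def two_class_dataset(n_minutes=4, seed=0):
    return synthesize_training_set(
        n_minutes=n_minutes, snr_db=20.0, seed=seed, rates={CallType.DC: 10.0}
    )


class TestTrain:
    def test_two_class_toy_learns(self):
        """Background vs distress calls at 20 dB SNR: held-out balanced
        accuracy over the two present classes must clearly beat chance."""
        cfg = tiny_config(seed=1, epochs=10, learning_rate=3e-3)
        model = build_model(cfg)
        model, history = train(model, two_class_dataset(4, seed=2), cfg)
        assert history[-1] < history[0]
        res = evaluate(model, two_class_dataset(1, seed=77))
        recalls = [res["per_class_recall"]["background"], res["per_class_recall"]["DC"]]
        assert np.mean(recalls) > 0.9

    def test_training_is_deterministic(self):
        data = two_class_dataset(1, seed=3)
        runs = []
        for _ in range(2):
            cfg = tiny_config(seed=5, epochs=2)
            model = build_model(cfg)
            _, hist = train(model, data, cfg)
            runs.append(hist[-1])
        assert runs[0] == runs[1]

    def test_single_class_dataset_refused(self):
        rng = np.random.default_rng(0)
        data = LabeledDataset(
            rng.normal(size=(8, 24, 64)).astype(np.float32),
            np.zeros((8, 1), dtype=np.int64),
            np.full(8, 7.0),
        )
        cfg = tiny_config()
        with pytest.raises(ValueError, match="2 classes"):
            train(build_model(cfg), data, cfg)

    def test_age_head_ablation_does_not_hurt_classes(self):
        """With the age loss disabled the class performance stays within
        noise of the default weight (3 seeds)."""
        data = two_class_dataset(2, seed=4)
        held = two_class_dataset(1, seed=88)
        accs = {}
        for w in (0.0, 0.1):
            vals = []
            for seed in (0, 1, 2):
                cfg = tiny_config(seed=seed, epochs=6, learning_rate=3e-3, age_loss_weight=w)
                model = build_model(cfg)
                model, _ = train(model, data, cfg)
                r = evaluate(model, held)
                vals.append(
                    0.5 * (r["per_class_recall"]["background"] + r["per_class_recall"]["DC"])
                )
            accs[w] = np.mean(vals)
        assert abs(accs[0.0] - accs[0.1]) < 0.15


class StubModel:
    """Deterministic stand-in emitting prescribed logits for evaluate()."""

    def __init__(self, fn):
        self.fn = fn

    def forward(self, x, train=False):
        return self.fn(x)


class TestEvaluate:
    def make_data(self, n=60, steps=5, seed=0):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 6, size=(n, steps))
        feats = labels[:, None, :].repeat(24, axis=2).transpose(0, 2, 1).repeat(64 // steps + 1, axis=2)[:, :, :64]
        return LabeledDataset(feats.astype(np.float32), labels.astype(np.int64), np.full(n, 7.0))

    def test_perfect_predictions_score_one(self):
        data = self.make_data()

        def oracle(x):
            lab = x[:, ::24, 0].astype(int)  # features encode the label
            out = np.full((x.shape[0], 7, lab.shape[1]), -10.0, dtype=np.float32)
            for i in range(x.shape[0]):
                for t in range(lab.shape[1]):
                    out[i, lab[i, t], t] = 10.0
            return out

        res = evaluate(StubModel(oracle), data)
        assert res["balanced_accuracy"] == 1.0

    def test_random_predictions_near_chance(self):
        data = self.make_data(n=400, steps=10, seed=1)
        rng = np.random.default_rng(2)

        def noise(x):
            return rng.normal(size=(x.shape[0], 7, x.shape[1] // 24)).astype(np.float32)

        res = evaluate(StubModel(noise), data)
        assert res["balanced_accuracy"] == pytest.approx(1 / 6, abs=0.04)

    def test_confusion_row_sums_equal_support(self):
        data = self.make_data(n=50, steps=4, seed=3)
        rng = np.random.default_rng(4)
        res = evaluate(
            StubModel(lambda x: rng.normal(size=(x.shape[0], 7, x.shape[1] // 24)).astype(np.float32)),
            data,
        )
        counts = np.bincount(data.labels.ravel(), minlength=6)
        assert np.array_equal(res["confusion_matrix"].sum(axis=1), counts)

    def test_empty_dataset_rejected(self):
        data = LabeledDataset(
            np.zeros((0, 24, 64), np.float32), np.zeros((0, 1), np.int64), np.zeros(0)
        )
        with pytest.raises(ValueError, match="empty"):
            evaluate(StubModel(lambda x: x), data)


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path):
        cfg = tiny_config(seed=6, epochs=1)
        model = build_model(cfg)
        _, _ = train(model, two_class_dataset(1, seed=5), cfg)
        spec = random_spec(96, 11)
        before = infer(model, spec).scores
        save_model(model, tmp_path / "m.npz")
        back = load_model(tmp_path / "m.npz")
        assert np.allclose(infer(back, spec).scores, before, atol=1e-7)
        assert back.config.channels == model.config.channels
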