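"""Architecture sizing, shape laws, training behavior, checkpoints."""

import numpy as np
import pytest

from microsleep import (
    ConfigurationError,
    ModelSpec,
    SUPPORTED_WINDOWS_S,
    TrainConfig,
    build_cnn,
    build_cnn_lstm,
    load_model,
    n_repeated_blocks,
    save_model,
    train,
)
from microsleep.model import N_FIXED_BLOCKS, map_two_class
from microsleep.nn import Conv1d, MaxPool1d
from microsleep.windowing import Batch


class TestBlockCounts:
    @pytest.mark.parametrize("window,expected", [(2, 3), (4, 4), (8, 5), (16, 6), (32, 7)])
    def test_repetition_ladder(self, window, expected):
        assert n_repeated_blocks(window) == expected

    def test_doubling_law(self):
        for w in (2, 4, 8, 16):
            assert n_repeated_blocks(2 * w) == n_repeated_blocks(w) + 1

    @pytest.mark.parametrize("window", [1, 3, 7, 64])
    def test_unsupported_window_rejected(self, window):
        with pytest.raises(ConfigurationError):
            n_repeated_blocks(window)


class TestShapeLaw:
    @pytest.mark.parametrize("window", SUPPORTED_WINDOWS_S)
    def test_final_temporal_extent_is_one(self, window):
        """Symbolic propagation vs an actual forward pass through the blocks."""
        model = build_cnn(ModelSpec(kind="cnn", window_s=window), seed=0)
        assert model.final_temporal_extent == 1
        # independent oracle: push a real array through the conv/pool stack
        x = np.random.default_rng(0).normal(size=(2, 3, window * 200))
        h = x
        observed = []
        for layer in model.net.layers:
            h = layer.forward(h)
            if isinstance(layer, MaxPool1d):
                observed.append(h.shape[-1])
            if not isinstance(h, np.ndarray) or h.ndim != 3:
                break
        assert observed == model.block_output_lengths
        assert observed[-1] == 1

    def test_block_count_matches_rule(self):
        for w in SUPPORTED_WINDOWS_S:
            model = build_cnn(ModelSpec(kind="cnn", window_s=w), seed=0)
            n_conv = sum(isinstance(l, Conv1d) for l in model.net.layers)
            assert n_conv == N_FIXED_BLOCKS + n_repeated_blocks(w)

    def test_unsupported_window_configuration_error(self):
        with pytest.raises(ConfigurationError):
            ModelSpec(kind="cnn", window_s=7)


class TestCnnOutputs:
    def test_probabilities_sum_to_one(self, rng):
        model = build_cnn(ModelSpec(kind="cnn", window_s=16), seed=0)
        p = model.predict(rng.normal(size=(4, 3, 3200)))
        assert p.shape == (4, 4)
        assert (p >= 0).all()
        assert np.abs(p.sum(axis=1) - 1.0).max() < 1e-6

    def test_single_channel_input(self, rng):
        model = build_cnn(ModelSpec(kind="cnn", window_s=2, in_channels=1), seed=0)
        p = model.predict(rng.normal(size=(2, 1, 400)))
        assert p.shape == (2, 4)

    def test_same_seed_same_weights(self):
        a = build_cnn(ModelSpec(kind="cnn", window_s=2), seed=5)
        b = build_cnn(ModelSpec(kind="cnn", window_s=2), seed=5)
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa, pb)


class TestCnnLstm:
    def test_window_enumeration(self):
        model = build_cnn_lstm(ModelSpec(kind="cnn_lstm", n_classes=2), seed=0)
        centers = model.window_centers(2000)  # 10 s at 200 Hz
        assert len(centers) == 37             # (2000-200)/50 + 1
        assert centers[0] == 100

    def test_sequence_probabilities(self, rng):
        model = build_cnn_lstm(ModelSpec(kind="cnn_lstm", n_classes=2), seed=0)
        p = model.predict(rng.normal(size=(2, 5, 3, 200)))
        assert p.shape == (2, 5, 2)
        assert np.abs(p.sum(axis=2) - 1.0).max() < 1e-6

    def test_too_short_recording_rejected(self):
        model = build_cnn_lstm(ModelSpec(kind="cnn_lstm", n_classes=2), seed=0)
        with pytest.raises(Exception):
            model.window_centers(100)

    def test_two_class_target_mapping(self):
        labels = np.array([0, 1, 2, 3, 4, 1])  # W, MSE, MSEc, ED, SLEEP, MSE
        assert map_two_class(labels).tolist() == [0, 1, 0, 0, 0, 1]


def _separable_batches(n_batches=20, batch=32, seed=0):
    """Two classes distinguished by the sign of a strong mean offset."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_batches):
        y = rng.integers(0, 2, batch)
        x = rng.normal(scale=0.1, size=(batch, 1, 400)) + (2 * y - 1)[:, None, None] * 0.5
        out.append(Batch(x=x, y=y, centers=np.zeros(batch, dtype=int),
                         sources=np.zeros(batch, dtype=int)))
    return out


class TestTraining:
    def test_loss_decreases_on_separable_problem(self):
        model = build_cnn(ModelSpec(kind="cnn", window_s=2, in_channels=1,
                                    n_classes=2), seed=0)
        hist = train(model, _separable_batches(), TrainConfig(iterations=1))
        assert np.mean(hist[-3:]) < hist[0]

    def test_zero_learning_rate_freezes_loss(self):
        model = build_cnn(ModelSpec(kind="cnn", window_s=2, in_channels=1,
                                    n_classes=2, noise_sd=0.0, dropout=0.0), seed=0)
        batches = _separable_batches(n_batches=4)
        hist = train(model, lambda it: iter([batches[0]] * 4),
                     TrainConfig(learning_rate=0.0, iterations=1))
        assert np.ptp(hist) < 1e-9

    def test_same_seed_reproducible_history(self):
        specs = ModelSpec(kind="cnn", window_s=2, in_channels=1, n_classes=2)
        h = []
        for _ in range(2):
            model = build_cnn(specs, seed=3)
            h.append(train(model, _separable_batches(5), TrainConfig(iterations=1)))
        assert h[0] == h[1]

    def test_one_shot_iterable_with_multiple_iterations_rejected(self):
        model = build_cnn(ModelSpec(kind="cnn", window_s=2, in_channels=1,
                                    n_classes=2), seed=0)
        with pytest.raises(Exception):
            train(model, _separable_batches(2), TrainConfig(iterations=3))

    def test_gradient_clipping_applies_to_lstm_training(self, rng):
        model = build_cnn_lstm(ModelSpec(kind="cnn_lstm", n_classes=2, seq_len=4),
                               seed=0)
        x = rng.normal(size=(2, 4, 3, 200))
        y = rng.integers(0, 2, size=(2, 4))
        batches = [Batch(x=x, y=y, centers=np.zeros(2, dtype=int),
                         sources=np.zeros(2, dtype=int))]
        hist = train(model, batches, TrainConfig(iterations=1, grad_clip_norm=1.0))
        assert np.isfinite(hist).all()


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, rng):
        model = build_cnn(ModelSpec(kind="cnn", window_s=2), seed=0)
        x = rng.normal(size=(3, 3, 400))
        before = model.predict(x)
        save_model(model, tmp_path / "ck.npz")
        loaded = load_model(tmp_path / "ck.npz")
        assert np.allclose(loaded.predict(x), before)
        assert loaded.spec == model.spec

    def test_cnn_lstm_round_trip(self, tmp_path, rng):
        model = build_cnn_lstm(ModelSpec(kind="cnn_lstm", n_classes=2), seed=0)
        x = rng.normal(size=(1, 4, 3, 200))
        before = model.predict(x)
        save_model(model, tmp_path / "l.npz")
        assert np.allclose(load_model(tmp_path / "l.npz").predict(x), before)
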