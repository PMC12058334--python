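"""Classifier construction, training contracts and video-level voting.

The expensive learning-performance check lives in the acceptance suite;
here a micro 16x16 spatial profile exercises the training loop end to end.
"""

from dataclasses import replace

import numpy as np
import pytest

from speckleflow.conditions import FlowCondition
from speckleflow.classifier import (
    ModelConfig, TrainConfig, build_model, load_checkpoint, predict_chunks,
    save_checkpoint, train, vote_video,
)
from speckleflow.preprocess import Chunk, DatasetSplit


def _micro_model(n_classes=4, seed=0):
    cfg = ModelConfig(stem_filters=4, block_channels=(8,), n_classes=n_classes)
    return build_model(cfg, (3, 16, 16, 16), seed=seed)


def _chunks(labels, seed=0, n_frames=16, hw=16):
    """Synthetic uint8 chunks whose mean brightness varies with the label."""
    rng = np.random.default_rng(seed)
    out = []
    for i, lab in enumerate(labels):
        base = 40 + 50 * int(lab)
        frames = rng.integers(base, base + 20, (n_frames, hw, hw)).astype(np.uint8)
        out.append(Chunk(raw_frames=frames, label=FlowCondition(lab),
                         video_id=f"v{i}", start_frame=0))
    return out


class TestBuildModel:
    def test_output_is_probability_vector(self):
        from speckleflow import nn
        model = _micro_model()
        x = np.random.default_rng(0).random((2, 3, 16, 16, 16), dtype=np.float32)
        probs = nn.softmax(model.forward(x, training=False))
        assert probs.shape == (2, 4)
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-5)

    def test_batch_order_equivariance(self):
        from speckleflow import nn
        model = _micro_model()
        x = np.random.default_rng(1).random((3, 3, 16, 16, 16), dtype=np.float32)
        out = model.forward(x, training=False)
        flipped = model.forward(x[::-1].copy(), training=False)
        assert np.allclose(out[::-1], flipped, atol=1e-5)

    def test_same_seed_same_init_and_output(self):
        x = np.random.default_rng(2).random((1, 3, 16, 16, 16), dtype=np.float32)
        a = _micro_model(seed=5).forward(x, training=False)
        b = _micro_model(seed=5).forward(x, training=False)
        assert np.array_equal(a, b)

    def test_too_small_input_names_stage(self):
        cfg = ModelConfig(stem_filters=4, block_channels=(8, 8, 8), n_classes=4)
        with pytest.raises(ValueError, match="block"):
            build_model(cfg, (3, 8, 8, 8))

    def test_non_decreasing_schedule_enforced(self):
        with pytest.raises(ValueError):
            ModelConfig(stem_filters=24, block_channels=(16,))


class TestTrain:
    def test_zero_epochs_is_a_no_op(self):
        model = _micro_model()
        before = {k: v.copy() for k, v in model.named_params().items()}
        chunks = _chunks([0, 1, 2, 3])
        split = DatasetSplit(chunks, [], [])
        model, history = train(model, split, TrainConfig(epochs=0))
        assert len(history) == 0
        for k, v in model.named_params().items():
            assert np.array_equal(v, before[k])

    def test_missing_class_is_reported(self):
        split = DatasetSplit(_chunks([0, 1, 1, 0]), [], [])
        with pytest.raises(ValueError, match="MEDIUM"):
            train(_micro_model(), split, TrainConfig(epochs=1))

    def test_training_is_deterministic(self):
        labels = [0, 1, 2, 3] * 2
        results = []
        for _ in range(2):
            split = DatasetSplit(_chunks(labels), [], _chunks([0, 1, 2, 3], seed=9))
            model = _micro_model(seed=3)
            model, history = train(model, split, TrainConfig(epochs=2, seed=3))
            results.append((history.val_accuracy, predict_chunks(model, split.test_chunks)))
        assert results[0][0] == results[1][0]
        assert np.array_equal(results[0][1], results[1][1])

    def test_history_length_and_loss_decrease_on_separable_data(self):
        labels = [0, 1, 2, 3] * 4
        split = DatasetSplit(_chunks(labels), [], [])
        model, history = train(_micro_model(), split, TrainConfig(epochs=5, seed=1))
        assert len(history) == 5
        assert history.train_loss[-1] < history.train_loss[0]


class TestPredict:
    def test_empty_chunk_list(self):
        assert predict_chunks(_micro_model(), []).shape == (0, 4)

    def test_duplicated_chunk_identical_probabilities(self):
        model = _micro_model()
        chunk = _chunks([2])[0]
        probs = predict_chunks(model, [chunk, chunk])
        assert np.array_equal(probs[0], probs[1])
        assert probs[0].sum() == pytest.approx(1.0, abs=1e-6)


class TestVoteVideo:
    def test_majority_wins(self):
        assert vote_video([FlowCondition.HIGH, FlowCondition.HIGH,
                           FlowCondition.LOW]) == FlowCondition.HIGH

    def test_tie_goes_to_lower_flow(self):
        assert vote_video([FlowCondition.ZERO, FlowCondition.HIGH]) == FlowCondition.ZERO
        assert vote_video([3, 1]) == FlowCondition.LOW

    def test_single_chunk(self):
        assert vote_video([FlowCondition.MEDIUM]) == FlowCondition.MEDIUM

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            vote_video([])


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path):
        model = _micro_model(seed=8)
        chunks = _chunks([0, 3])
        before = predict_chunks(model, chunks)
        save_checkpoint(model, tmp_path / "m.ckpt", TrainConfig())
        restored = load_checkpoint(tmp_path / "m.ckpt")
        after = predict_chunks(restored, chunks)
        assert np.allclose(before, after, atol=1e-6)
        assert (tmp_path / "m.json").exists()
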