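"""Training protocol: relabel/remap, augmentation, LR schedule, loop
bookkeeping and seeded reproducibility."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitotime.networks import FrameSpec, build_base_model
from mitotime.pipeline import build_model
from mitotime.synthetic_mitosis import DatasetSplit, SimConfig, generate_dataset
from mitotime.training import (
    TrainConfig,
    augment_sequence,
    lr_at,
    predict_sequence,
    relabel_recovery,
    remap_predictions,
    train,
)


def monotone_labels(draw_ints):
    """Build a monotone 3-class label vector from three run lengths."""
    a, b, c = draw_ints
    return np.concatenate([np.full(a, 1), np.full(b, 2), np.full(c, 3)])


class TestRelabelRecovery:
    def test_worked_example(self):
        labels = np.array([1, 1, 2, 2, 3, 3, 3, 3, 3])
        out = relabel_recovery(labels, K=2)
        np.testing.assert_array_equal(out, [1, 1, 2, 2, 3, 3, 3, 1, 1])

    def test_large_K_leaves_labels_unchanged(self):
        labels = np.array([1, 2, 3, 3, 3])
        np.testing.assert_array_equal(relabel_recovery(labels, K=10), labels)

    def test_no_post_mitosis_unchanged(self):
        labels = np.array([1, 1, 2, 2])
        np.testing.assert_array_equal(relabel_recovery(labels, K=1), labels)

    def test_non_monotone_raises(self):
        with pytest.raises(ValueError):
            relabel_recovery(np.array([1, 3, 2]), K=1)


class TestRemapPredictions:
    def test_worked_example(self):
        pred = np.array([1, 1, 2, 2, 3, 1, 1])
        np.testing.assert_array_equal(remap_predictions(pred),
                                      [1, 1, 2, 2, 3, 3, 3])

    def test_no_mitosis_passes_through(self):
        np.testing.assert_array_equal(remap_predictions(np.array([1, 1, 1])),
                                      [1, 1, 1])

    def test_no_trailing_interphase_unchanged(self):
        np.testing.assert_array_equal(remap_predictions(np.array([1, 2, 3])),
                                      [1, 2, 3])

    @settings(max_examples=200, deadline=None)
    @given(st.tuples(st.integers(1, 10), st.integers(1, 10), st.integers(1, 20)),
           st.integers(0, 25))
    def test_round_trip_recovers_annotation(self, runs, K):
        """A perfect predictor of relabeled targets, passed through the
        remapping, reproduces the original annotation on every frame."""
        labels = monotone_labels(runs)
        relabeled = relabel_recovery(labels, K)
        recovered = remap_predictions(relabeled)
        np.testing.assert_array_equal(recovered, labels)


class TestAugmentation:
    def test_identity_draw(self, desk_sim_config):
        seq = generate_dataset(2, desk_sim_config, seed=0).train[0]

        class FixedRng:
            def integers(self, lo, hi):
                return 0

        aug = augment_sequence(seq, FixedRng())
        np.testing.assert_array_equal(aug.frames, seq.frames)
        np.testing.assert_array_equal(aug.masks, seq.masks)

    def test_flip_is_involution(self, desk_sim_config, rng):
        seq = generate_dataset(2, desk_sim_config, seed=0).train[0]

        class FlipRng:
            def __init__(self):
                self.calls = 0

            def integers(self, lo, hi):
                self.calls += 1
                return 0 if self.calls % 2 == 1 else 1  # rot0 + h-flip

        once = augment_sequence(seq, FlipRng())
        twice = augment_sequence(once, FlipRng())
        np.testing.assert_array_equal(twice.frames, seq.frames)

    def test_rot90_matches_hand_rotation(self):
        from mitotime.training import AugmentedSample

        frames = np.array([[[1, 2], [3, 4]]], dtype=np.uint8)
        sample = AugmentedSample(frames, frames.copy(), np.array([1]))

        class RotRng:
            def __init__(self):
                self.calls = 0

            def integers(self, lo, hi):
                self.calls += 1
                return 1 if self.calls == 1 else 0  # rot90 once, no flip

        out = augment_sequence(sample, RotRng())
        np.testing.assert_array_equal(out.frames[0], [[2, 4], [1, 3]])

    def test_labels_invariant(self, desk_sim_config, rng):
        seq = generate_dataset(2, desk_sim_config, seed=1).train[0]
        for _ in range(5):
            aug = augment_sequence(seq, rng)
            np.testing.assert_array_equal(aug.labels, seq.labels)
            assert aug.frames.shape == seq.frames.shape


class TestLrSchedule:
    def test_published_values(self):
        cfg = TrainConfig(lr=0.001)
        assert lr_at(0, cfg) == pytest.approx(0.001)
        assert lr_at(2499, cfg) == pytest.approx(0.001)
        assert lr_at(2500, cfg) == pytest.approx(0.0001)

    def test_two_drops(self):
        cfg = TrainConfig(lr=0.01)
        assert lr_at(5000, cfg) == pytest.approx(0.0001)


@pytest.fixture(scope="module")
def micro_split():
    cfg = SimConfig.desk(sequence_length=10, frame_size=32,
                         stage_duration_ranges={"interphase": (2, 3),
                                                "mitosis": (2, 3),
                                                "post_mitosis": (4, 6)},
                         recovery_onset=(3, 4))
    return generate_dataset(6, cfg, seed=5, ratio=0.67)


class TestTrainLoop:
    def micro_model(self, seed=0):
        return build_base_model(FrameSpec(32, 32, 3), 3, channels=(2, 4, 8),
                                seed=seed)

    def test_history_bookkeeping(self, micro_split):
        model = self.micro_model()
        cfg = TrainConfig(model_kind="base", batch=2, lr=0.01, epochs=1, seed=0)
        _, history = train(model, micro_split, cfg)
        iters = [h for h in history if "L_tot" in h]
        assert len(iters) == 2  # ceil(4 sequences / batch 2)
        assert {"L_track", "L_cls", "L_tot", "lr"} <= set(iters[0])
        assert any(h.get("event") == "epoch_end" for h in history)

    def test_frame_classifier_history_has_no_tracking_loss(self, micro_split):
        model = build_model("frame_classifier", FrameSpec(32, 32, 3), 3,
                            seed=0)
        cfg = TrainConfig(model_kind="frame_classifier", batch=16, lr=0.01,
                          epochs=1, seed=0)
        _, history = train(model, micro_split, cfg)
        iters = [h for h in history if "L_tot" in h]
        assert iters and all("L_track" not in h for h in iters)

    def test_loss_decreases_over_training(self, micro_split):
        model = self.micro_model(seed=1)
        cfg = TrainConfig(model_kind="base", batch=2, lr=0.02, epochs=10, seed=1)
        _, history = train(model, micro_split, cfg)
        losses = [h["L_tot"] for h in history if "L_tot" in h]
        n = max(len(losses) // 10, 1)
        assert np.mean(losses[-n:]) < np.mean(losses[:n])

    def test_seeded_reproducibility(self, micro_split):
        runs = []
        for _ in range(2):
            model = self.micro_model(seed=2)
            cfg = TrainConfig(model_kind="base", batch=2, lr=0.01, epochs=2,
                              seed=3)
            _, history = train(model, micro_split, cfg)
            runs.append([h["L_tot"] for h in history if "L_tot" in h])
        np.testing.assert_allclose(runs[0], runs[1], rtol=1e-7)

    def test_empty_split_raises(self):
        model = self.micro_model()
        with pytest.raises(ValueError):
            train(model, DatasetSplit([], [], 0.85),
                  TrainConfig(model_kind="base"))

    def test_batched_equals_sequential_forward(self, micro_split):
        """Sequence isolation: evaluating sequences in one batch equals
        evaluating them one at a time."""
        from mitotime.networks import forward_sequence
        from mitotime.training import frames_to_input

        model = self.micro_model(seed=4)
        model.eval()
        seqs = micro_split.train[:2]
        x = np.stack([frames_to_input(s.frames) for s in seqs])
        batched = model.forward_batch(x)["scores"].data
        for b, seq in enumerate(seqs):
            single = forward_sequence(model, frames_to_input(seq.frames))
            np.testing.assert_allclose(batched[b], single["scores"], atol=1e-5)


class _StubModel:
    """Fixed-score model for exercising the prediction path."""

    n_class = 3
    frame_spec = FrameSpec(8, 8, 3)
    training = False

    def __init__(self, scores):
        self._scores = np.asarray(scores, dtype=np.float32)

    def eval(self):
        return self

    def train(self):
        return self

    def forward_batch(self, x):
        from mitotime.nn.tensor import Tensor

        return {"scores": Tensor(self._scores[None]),
                "embeddings": Tensor(self._scores[None])}


class TestPredictSequence:
    def test_argmax_and_tie_break_toward_lowest_stage(self):
        stub = _StubModel([[0.9, 0.2, 0.1],   # clear stage 1
                           [0.4, 0.4, 0.2],   # tie 1 vs 2 -> stage 1
                           [0.1, 0.8, 0.2]])  # clear stage 2
        frames = np.zeros((3, 8, 8), dtype=np.uint8)
        pred = predict_sequence(stub, frames, remap=False)
        np.testing.assert_array_equal(pred, [1, 1, 2])

    def test_remap_applied_by_default_for_three_class(self):
        stub = _StubModel([[0.1, 0.9, 0.1],
                           [0.2, 0.1, 0.9],
                           [0.9, 0.1, 0.1]])  # trailing interphase
        frames = np.zeros((3, 8, 8), dtype=np.uint8)
        np.testing.assert_array_equal(predict_sequence(stub, frames), [2, 3, 3])

    def test_predictions_are_valid_labels(self):
        cfg = SimConfig.desk(sequence_length=10, frame_size=32,
                             stage_duration_ranges={"interphase": (2, 3),
                                                    "mitosis": (2, 3),
                                                    "post_mitosis": (4, 6)},
                             recovery_onset=(3, 4))
        split = generate_dataset(2, cfg, seed=9)
        model = build_base_model(FrameSpec(32, 32, 3), 3, channels=(2, 4, 8),
                                 seed=5)
        pred = predict_sequence(model, split.train[0].frames)
        assert pred.shape == (10,)
        assert set(np.unique(pred)) <= {1, 2, 3}
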