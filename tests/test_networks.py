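"""Architecture contracts: shapes, causality, frame independence."""

import numpy as np
import pytest

from mitotime.networks import (
    BackboneSpec,
    FrameSpec,
    build_base_model,
    build_frame_classifier,
    build_time_encoded_model,
    forward_sequence,
    load_checkpoint,
    save_checkpoint,
)
from mitotime.training import frames_to_input


def tiny_sequence(t=3, size=64, seed=0):
    rng = np.random.default_rng(seed)
    return rng.random((t, 3, size, size), dtype=np.float32)


class TestShapeContracts:
    def test_full_spec_224_gives_512x7x7_features(self):
        model = build_time_encoded_model(FrameSpec(224, 224, 3),
                                         BackboneSpec.full(), 3, seed=0)
        out = forward_sequence(model, tiny_sequence(1, 224))
        assert out["features"].shape == (1, 512, 7, 7)
        assert out["tracks"].shape == (1, 3, 224, 224)
        assert out["scores"].shape == (1, 3)

    def test_reduced_spec_64_gives_64x2x2_features(self, tiny_frame_spec,
                                                   reduced_backbone):
        model = build_time_encoded_model(tiny_frame_spec, reduced_backbone,
                                         3, seed=0)
        out = forward_sequence(model, tiny_sequence(2))
        assert out["features"].shape == (2, 64, 2, 2)
        assert out["tracks"].shape == (2, 3, 64, 64)

    def test_downscale_arithmetic_over_random_valid_specs(self):
        """Feature maps are always stage_channels[-1] x H/32 x W/32."""
        rng = np.random.default_rng(0)
        for _ in range(5):
            base = int(rng.integers(2, 5))
            chans = tuple(base * 2 ** i for i in range(4))
            spec = BackboneSpec(stage_channels=chans, gru_channels=chans[1:],
                                decoder_channels=(chans[2], chans[1], chans[0], 3),
                                head_conv_channels=16, head_hidden=8)
            size = int(rng.choice([32, 64, 96]))
            model = build_time_encoded_model(FrameSpec(size, size, 3), spec,
                                             3, seed=1)
            out = forward_sequence(model, tiny_sequence(1, size))
            assert out["features"].shape == (1, chans[-1], size // 32, size // 32)
            assert out["tracks"].shape == (1, 3, size, size)

    def test_n_class_sets_score_width(self, tiny_frame_spec, reduced_backbone):
        model = build_time_encoded_model(tiny_frame_spec, reduced_backbone,
                                         6, seed=0)
        out = forward_sequence(model, tiny_sequence(1))
        assert out["scores"].shape == (1, 6)

    def test_indivisible_frame_size_raises(self, reduced_backbone):
        with pytest.raises(ValueError):
            build_time_encoded_model(FrameSpec(70, 70, 3), reduced_backbone, 3)

    def test_inconsistent_gru_widths_raise(self):
        with pytest.raises(ValueError):
            BackboneSpec(stage_channels=(8, 16, 32, 64), gru_channels=(8, 16, 32))

    def test_scores_and_tracks_in_unit_interval(self, tiny_frame_spec,
                                                reduced_backbone):
        model = build_time_encoded_model(tiny_frame_spec, reduced_backbone,
                                         3, seed=2)
        out = forward_sequence(model, tiny_sequence(2, seed=3))
        for key in ("scores", "tracks"):
            assert np.all(out[key] > 0.0) and np.all(out[key] < 1.0)


class TestCausality:
    def test_prepending_frame_changes_recurrent_outputs_only(self,
                                                             tiny_frame_spec,
                                                             reduced_backbone):
        """Recurrent outputs depend on the past; the frame classifier's
        outputs are invariant to other frames."""
        frames = tiny_sequence(4, seed=5)
        extra = tiny_sequence(1, seed=6)
        longer = np.concatenate([extra, frames])

        te = build_time_encoded_model(tiny_frame_spec, reduced_backbone, 3, seed=7)
        out_a = forward_sequence(te, frames)["scores"]
        out_b = forward_sequence(te, longer)["scores"][1:]
        assert not np.allclose(out_a, out_b, atol=1e-6)

        fc = build_frame_classifier(tiny_frame_spec, 3,
                                    stage_channels=(8, 16, 32, 64), seed=7)
        fc.eval()
        sc_a = fc.forward(frames)[0].data
        sc_b = fc.forward(longer)[0].data[1:]
        np.testing.assert_allclose(sc_a, sc_b, atol=1e-6)

    def test_outputs_invariant_to_future_frames(self, tiny_frame_spec,
                                                reduced_backbone):
        model = build_time_encoded_model(tiny_frame_spec, reduced_backbone,
                                         3, seed=8)
        frames = tiny_sequence(4, seed=9)
        altered = frames.copy()
        altered[-1] += 0.3  # change only the final frame
        out_orig = forward_sequence(model, frames)["scores"]
        out_alt = forward_sequence(model, altered)["scores"]
        np.testing.assert_allclose(out_orig[:-1], out_alt[:-1], atol=1e-6)
        assert not np.allclose(out_orig[-1], out_alt[-1], atol=1e-6)

    def test_single_frame_equals_zero_state_step(self, tiny_frame_spec,
                                                 reduced_backbone):
        model = build_time_encoded_model(tiny_frame_spec, reduced_backbone,
                                         3, seed=10)
        model.eval()
        frames = tiny_sequence(1, seed=11)
        seq_out = forward_sequence(model, frames)["scores"]
        from mitotime.nn.tensor import Tensor
        _, _, scores, _, _ = model.forward_step(Tensor(frames), model.init_state(1))
        np.testing.assert_allclose(seq_out, scores.data, atol=1e-6)


class TestFrameClassifier:
    def test_output_width_matches_classes(self, tiny_frame_spec):
        fc = build_frame_classifier(tiny_frame_spec, 6,
                                    stage_channels=(8, 16, 32, 64), seed=0)
        scores, _ = fc.forward(tiny_sequence(2))
        assert scores.shape == (2, 6)

    def test_frame_permutation_equivariance(self, tiny_frame_spec):
        fc = build_frame_classifier(tiny_frame_spec, 3,
                                    stage_channels=(8, 16, 32, 64), seed=1)
        fc.eval()
        frames = tiny_sequence(4, seed=2)
        perm = np.array([2, 0, 3, 1])
        direct = fc.forward(frames[perm])[0].data
        permuted = fc.forward(frames)[0].data[perm]
        np.testing.assert_allclose(direct, permuted, atol=1e-6)

    def test_pretrained_without_weights_raises(self, tiny_frame_spec):
        with pytest.raises(ValueError):
            build_frame_classifier(tiny_frame_spec, 3, pretrained=True)


class TestBaseModel:
    def test_accepts_96x96_and_conserves_shape(self):
        model = build_base_model(FrameSpec(96, 96, 3), 3, channels=(4, 8, 16),
                                 seed=0)
        out = forward_sequence(model, tiny_sequence(2, 96))
        assert out["tracks"].shape == (2, 3, 96, 96)
        assert out["scores"].shape == (2, 3)

    def test_temporal_dependence(self):
        model = build_base_model(FrameSpec(64, 64, 3), 3, channels=(4, 8, 16),
                                 seed=1)
        frames = tiny_sequence(3, seed=12)
        longer = np.concatenate([tiny_sequence(1, seed=13), frames])
        out_a = forward_sequence(model, frames)["scores"]
        out_b = forward_sequence(model, longer)["scores"][1:]
        assert not np.allclose(out_a, out_b, atol=1e-6)


class TestCheckpoints:
    def test_round_trip_preserves_outputs(self, tmp_path, tiny_frame_spec,
                                          reduced_backbone):
        model = build_time_encoded_model(tiny_frame_spec, reduced_backbone,
                                         3, seed=3)
        frames = tiny_sequence(2, seed=4)
        before = forward_sequence(model, frames)["scores"]
        save_checkpoint(model, tmp_path / "ckpt.npz")
        restored = load_checkpoint(tmp_path / "ckpt.npz")
        after = forward_sequence(restored, frames)["scores"]
        np.testing.assert_allclose(before, after, atol=1e-6)

    def test_sidecar_describes_model(self, tmp_path, tiny_frame_spec):
        import json
        fc = build_frame_classifier(tiny_frame_spec, 3,
                                    stage_channels=(8, 16, 32, 64), seed=0)
        save_checkpoint(fc, tmp_path / "fc.npz")
        cfg = json.loads((tmp_path / "fc.npz.json").read_text())
        assert cfg["kind"] == "frame_classifier"
        assert cfg["n_class"] == 3
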