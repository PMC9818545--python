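"""Fine-tuning head, training schedule, and feature extraction."""

import numpy as np
import pandas as pd
import pytest

from histopatch.features import (
    FeatureVector,
    FineTuneHead,
    TinyBackbone,
    TrainConfig,
    categorical_accuracy,
    concat_features,
    cross_entropy,
    extract_features,
    head_forward,
    one_hot,
    train_head,
)


class TestHeadForward:
    @pytest.mark.parametrize("shape", [(6, 6, 32), (9, 9, 8)])
    def test_gap_features_are_512_dim_for_any_spatial_map(self, shape):
        head = FineTuneHead(in_channels=shape[-1], seed=0)
        probs, feats = head_forward(np.random.default_rng(0).random(shape), head)
        assert feats.shape == (512,)
        assert probs.shape == (4,)
        assert probs.min() >= 0 and abs(probs.sum() - 1.0) < 1e-6

    def test_zero_weights_give_zero_features_and_uniform_probs(self):
        head = FineTuneHead(in_channels=8, seed=0)
        for layer in head.net.layers:
            for name in layer.params:
                layer.params[name][:] = 0.0
        probs, feats = head_forward(np.full((5, 5, 8), 0.7), head)
        assert np.allclose(feats, 0.0)
        assert np.allclose(probs, 0.25)

    def test_map_smaller_than_kernel_rejected(self):
        head = FineTuneHead(in_channels=4, seed=0)
        with pytest.raises(ValueError, match="kernel"):
            head_forward(np.ones((2, 2, 4)), head)


class TestLossesAndAccuracy:
    def test_cross_entropy_of_perfect_prediction_is_zero(self):
        assert cross_entropy([0, 1, 0, 0], [0, 1, 0, 0]) == pytest.approx(0.0, abs=1e-9)

    def test_cross_entropy_of_uniform_prediction_is_ln4(self):
        assert cross_entropy([1, 0, 0, 0], [0.25] * 4) == pytest.approx(np.log(4), abs=1e-9)

    def test_cross_entropy_half_mass_on_truth_is_ln2(self):
        assert cross_entropy([1, 0, 0, 0], [0.5, 0.5, 1e-12, 1e-12]) == pytest.approx(np.log(2), abs=1e-6)

    def test_categorical_accuracy_counts_argmax_matches(self):
        preds = one_hot(["normal", "benign", "insitu", "insitu"])
        assert categorical_accuracy(["normal", "benign", "insitu", "invasive"], preds) == 0.75
        assert categorical_accuracy(["normal"] * 4, one_hot(["normal"] * 4)) == 1.0
        assert categorical_accuracy(["invasive"] * 4, one_hot(["normal"] * 4)) == 0.0

    def test_argmax_tie_breaks_to_lowest_class(self):
        tied = np.array([[0.5, 0.5, 0.0, 0.0]])
        assert categorical_accuracy(["normal"], tied) == 1.0
        assert categorical_accuracy(["benign"], tied) == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            categorical_accuracy([], np.zeros((0, 4)))


class TestTrainHead:
    @pytest.fixture(scope="class")
    def trained(self, fixture_patches):
        backbone = TinyBackbone(seed=0)
        head = FineTuneHead(backbone.channels, seed=0)
        cfg = TrainConfig(max_epochs=10, seed=0)
        head, history = train_head(backbone, head, fixture_patches, None, cfg)
        return backbone, head, history

    def test_learns_separable_fixture_patches_above_chance(self, trained):
        _, _, history = trained
        assert history["train_acc"].iloc[-1] > 0.6  # far above the 0.25 chance level

    def test_lr_follows_iterative_decay_schedule(self, trained):
        _, _, history = trained
        cfg = TrainConfig(max_epochs=10, seed=0)
        d = cfg.effective_decay()
        expected = cfg.lr0 / (1 + d) ** np.arange(len(history))
        assert np.allclose(history["lr"].to_numpy(), expected, rtol=1e-12)

    def test_training_is_deterministic_given_seed(self, fixture_patches):
        subset = fixture_patches[::4]
        histories = []
        for _ in range(2):
            backbone = TinyBackbone(seed=1)
            head = FineTuneHead(backbone.channels, seed=1)
            _, h = train_head(backbone, head, subset, None, TrainConfig(max_epochs=3, seed=1))
            histories.append(h)
        pd.testing.assert_frame_equal(histories[0], histories[1])

    def test_missing_class_rejected(self, fixture_patches):
        only_two = [p for p in fixture_patches if p.label in ("normal", "invasive")]
        backbone = TinyBackbone(seed=0)
        head = FineTuneHead(backbone.channels, seed=0)
        with pytest.raises(ValueError, match="missing classes"):
            train_head(backbone, head, only_two, None, TrainConfig(max_epochs=1))

    def test_early_stopping_halts_on_flat_validation(self, fixture_patches):
        backbone = TinyBackbone(seed=0)
        head = FineTuneHead(backbone.channels, seed=0)
        cfg = TrainConfig(max_epochs=60, early_stop_patience=3, seed=0)
        _, history = train_head(backbone, head, fixture_patches, fixture_patches[::3], cfg)
        assert len(history) < 60

    def test_extracted_features_are_pure_and_aligned(self, trained, fixture_patches):
        backbone, head, _ = trained
        subset = fixture_patches[:6] + [fixture_patches[0]]  # duplicate first patch
        feats = extract_features(backbone, head, subset)
        assert all(f.values.shape == (512,) for f in feats)
        assert np.array_equal(feats[0].values, feats[-1].values)
        permuted = extract_features(backbone, head, subset[::-1])
        assert np.array_equal(permuted[-1].values, feats[0].values)

    def test_untrained_head_requires_explicit_flag(self, fixture_patches):
        backbone = TinyBackbone(seed=0)
        head = FineTuneHead(backbone.channels, seed=0)
        with pytest.raises(ValueError, match="untrained"):
            extract_features(backbone, head, fixture_patches[:2])
        feats = extract_features(backbone, head, fixture_patches[:2], allow_untrained=True)
        assert len(feats) == 2


class TestConcatFeatures:
    def _fv(self, ref, dim, source, seed):
        return FeatureVector(ref, np.random.default_rng(seed).random(dim), source)

    def test_three_512_vectors_concat_to_1536(self):
        lists = [[self._fv("p0", 512, f"b{k}", k)] for k in range(3)]
        out = concat_features(lists)
        assert out[0].values.shape == (1536,)
        assert out[0].source == "concat"
        assert np.array_equal(out[0].values[:512], lists[0][0].values)

    def test_single_backbone_is_identity(self):
        lst = [self._fv("p0", 8, "b", 0)]
        assert concat_features([lst]) is lst

    def test_order_matters_but_values_agree_as_multisets(self):
        a, b = [self._fv("p0", 4, "a", 1)], [self._fv("p0", 4, "b", 2)]
        ab = concat_features([a, b])[0].values
        ba = concat_features([b, a])[0].values
        assert not np.array_equal(ab, ba)
        assert np.allclose(np.sort(ab), np.sort(ba))

    def test_misaligned_patch_identities_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            concat_features([[self._fv("p0", 4, "a", 0)], [self._fv("p1", 4, "b", 0)]])
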