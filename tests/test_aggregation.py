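"""Frequency arrays, probability weighting, and the two-stage image models."""

import numpy as np
import pytest

from histopatch.aggregation import (
    FrequencyArray,
    OracleTwoClassModel,
    build_frequency_array,
    majority_vote_class,
    predict_image,
    train_four_class,
    train_two_class,
    weight_frequency,
)
from histopatch.ensemble import PatchClassProbabilities
from histopatch.io_dataset import CLASSES
from histopatch.nn import TrainConfig


def freq(counts4, ref="img") -> FrequencyArray:
    counts4 = np.asarray(counts4)
    return FrequencyArray(
        image_ref=ref,
        counts4=counts4,
        counts2=np.array([counts4[2] + counts4[3], counts4[0] + counts4[1]]),
        total=int(counts4.sum()),
    )


def patch_preds(class_indices, parent="img0"):
    preds = []
    for j, c in enumerate(class_indices):
        probs = np.full(4, 0.01)
        probs[c] = 0.97
        preds.append(PatchClassProbabilities(f"{parent}_r0_c{j}", probs, "ensemble"))
    return preds


IMG_CFG = TrainConfig(lr0=0.008, max_epochs=400, batch_size=16, seed=0)


def _training_freqs(rng_seed=0, per_class=10, total=35):
    """Frequency arrays with a dominant true class (>= 30 of 35 patches)."""
    rng = np.random.default_rng(rng_seed)
    freqs, labels = [], []
    for ci, label in enumerate(CLASSES):
        for i in range(per_class):
            dominant = int(rng.integers(30, total + 1))
            counts = np.zeros(4, dtype=int)
            counts[ci] = dominant
            rest = total - dominant
            others = [k for k in range(4) if k != ci]
            for k in others[:-1]:
                take = int(rng.integers(0, rest + 1))
                counts[k] += take
                rest -= take
            counts[others[-1]] += rest
            freqs.append(freq(counts, ref=f"{label}_{i}"))
            labels.append(label)
    return freqs, labels


class TestBuildFrequencyArray:
    def test_all_normal_patches(self):
        fa = build_frequency_array(patch_preds([0] * 35))
        assert fa.counts4.tolist() == [35, 0, 0, 0]
        assert fa.counts2.tolist() == [0, 35]
        assert fa.total == 35

    def test_worked_multiset_28_4_2_1(self):
        classes = [0] * 28 + [1] * 4 + [2] * 2 + [3] * 1
        fa = build_frequency_array(patch_preds(classes))
        assert fa.counts4.tolist() == [28, 4, 2, 1]
        assert fa.counts2.tolist() == [3, 32]  # insitu+invasive, normal+benign

    def test_count_conservation(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            classes = rng.integers(0, 4, size=35)
            fa = build_frequency_array(patch_preds(classes))
            assert fa.counts4.sum() == fa.counts2.sum() == 35

    def test_mixed_parents_rejected(self):
        preds = patch_preds([0], "a") + patch_preds([1], "b")
        with pytest.raises(ValueError, match="mix parent"):
            build_frequency_array(preds)

    def test_unexpected_patch_count_rejected(self):
        with pytest.raises(ValueError, match="expected 35"):
            build_frequency_array(patch_preds([0] * 12), expected_total=35)

    def test_soft_counting_sums_probabilities(self):
        fa = build_frequency_array(patch_preds([0, 0, 3]), soft=True)
        assert fa.counts4.sum() == pytest.approx(3.0)
        assert fa.counts4[0] > fa.counts4[3] > fa.counts4[1]


class TestWeightFrequency:
    def test_p_one_keeps_only_cancerous_counts(self):
        fa = weight_frequency(freq([10, 10, 10, 5]), 1.0)
        assert fa.weighted4.tolist() == [0, 0, 10, 5]

    def test_p_zero_keeps_only_noncancerous_counts(self):
        fa = weight_frequency(freq([10, 10, 10, 5]), 0.0)
        assert fa.weighted4.tolist() == [10, 10, 0, 0]

    def test_p_half_halves_everything(self):
        fa = weight_frequency(freq([28, 4, 2, 1]), 0.5)
        assert fa.weighted4.tolist() == [14.0, 2.0, 1.0, 0.5]

    def test_p_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="p_cancer"):
            weight_frequency(freq([35, 0, 0, 0]), 1.2)

    def test_monotone_in_cancer_probability(self):
        fa = freq([8, 9, 10, 8])
        previous = None
        for p in np.linspace(0.0, 1.0, 11):
            w = weight_frequency(fa, p).weighted4
            if previous is not None:
                assert (w[:2] <= previous[:2] + 1e-12).all()
                assert (w[2:] >= previous[2:] - 1e-12).all()
            previous = w


@pytest.fixture(scope="module")
def trained_models():
    freqs, labels = _training_freqs()
    cancerous = [l in ("insitu", "invasive") for l in labels]
    two_model, _ = train_two_class(freqs, cancerous, IMG_CFG)
    p = two_model.predict_batch(freqs)
    weighted = [weight_frequency(f, pi) for f, pi in zip(freqs, p)]
    four_model, _ = train_four_class(weighted, labels, IMG_CFG)
    return freqs, labels, cancerous, two_model, four_model


class TestTwoClassModel:
    def test_separable_counts_reach_95_percent_training_accuracy(self, trained_models):
        freqs, _, cancerous, two_model, _ = trained_models
        acc = np.mean((two_model.predict_batch(freqs) > 0.5) == np.asarray(cancerous))
        assert acc >= 0.95

    def test_balanced_arrays_all_receive_identical_probability(self, trained_models):
        _, _, _, two_model, _ = trained_models
        ps = {two_model.predict_p(freq([k, k, k, k])) for k in (1, 5, 8)}
        assert len({round(p, 12) for p in ps}) == 1

    def test_training_is_deterministic(self):
        freqs, labels = _training_freqs(rng_seed=3, per_class=5)
        cancerous = [l in ("insitu", "invasive") for l in labels]
        a, _ = train_two_class(freqs, cancerous, IMG_CFG)
        b, _ = train_two_class(freqs, cancerous, IMG_CFG)
        assert np.allclose(a.predict_batch(freqs), b.predict_batch(freqs))

    def test_single_class_rejected(self):
        freqs, _ = _training_freqs(per_class=2)
        with pytest.raises(ValueError, match="both"):
            train_two_class(freqs, [True] * len(freqs), IMG_CFG)


class TestFourClassModel:
    def test_dominant_count_arrays_reach_95_percent_accuracy(self, trained_models):
        freqs, labels, _, two_model, four_model = trained_models
        p = two_model.predict_batch(freqs)
        hits = 0
        for f, pi, label in zip(freqs, p, labels):
            probs = four_model.predict_probs(weight_frequency(f, pi))
            assert probs.sum() == pytest.approx(1.0, abs=1e-9)
            hits += CLASSES[int(probs.argmax())] == label
        assert hits / len(freqs) >= 0.95

    def test_missing_class_rejected(self):
        freqs, labels = _training_freqs(per_class=2)
        keep = [i for i, l in enumerate(labels) if l != "benign"]
        weighted = [weight_frequency(freqs[i], 0.5) for i in keep]
        with pytest.raises(ValueError, match="all classes"):
            train_four_class(weighted, [labels[i] for i in keep], IMG_CFG)


class TestPredictImage:
    def test_confident_invasive_patches_give_invasive_cancerous_image(self, trained_models):
        _, _, _, two_model, four_model = trained_models
        preds = patch_preds([3] * 35)
        result = predict_image(preds, two_model, four_model)
        assert result.predicted_class == "invasive"
        assert result.predicted_cancerous
        assert result.cancer_probability > 0.5

    def test_predicted_class_is_argmax_of_class_probs(self, trained_models):
        _, _, _, two_model, four_model = trained_models
        result = predict_image(patch_preds([0] * 20 + [1] * 15), two_model, four_model)
        assert result.predicted_class == CLASSES[int(result.class_probs.argmax())]

    def test_identical_patch_predictions_give_identical_output(self, trained_models):
        _, _, _, two_model, four_model = trained_models
        a = predict_image(patch_preds([2] * 35), two_model, four_model)
        b = predict_image(patch_preds([2] * 35), two_model, four_model)
        assert a.cancer_probability == b.cancer_probability
        assert np.array_equal(a.class_probs, b.class_probs)

    def test_oracle_binary_stage_confines_errors_to_superclass(self, trained_models):
        freqs, labels, cancerous, _, four_model = trained_models
        oracle = OracleTwoClassModel({f.image_ref: c for f, c in zip(freqs, cancerous)})
        for f, label, is_cancer in zip(freqs, labels, cancerous):
            weighted = weight_frequency(f, oracle.predict_p(f))
            pred = CLASSES[int(four_model.predict_probs(weighted).argmax())]
            assert (pred in ("insitu", "invasive")) == is_cancer


def test_majority_vote_baseline_with_lowest_index_ties():
    assert majority_vote_class(freq([20, 10, 3, 2])) == "normal"
    assert majority_vote_class(freq([10, 10, 10, 5])) == "normal"
    assert majority_vote_class(freq([0, 1, 4, 30])) == "invasive"
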