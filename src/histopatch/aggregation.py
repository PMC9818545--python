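"""Patch-to-image aggregation via frequency arrays and a two-stage network.

For each image the per-patch predicted classes are counted into a frequency
array ``counts4 = [normal, benign, insitu, invasive]`` (35 entries total in
the reference geometry) and a binary variant ``counts2 = [cancerous,
non-cancerous]`` with cancerous = insitu + invasive. Stage one — softmax
over counts2, one L2-regularized affine unit, sigmoid — yields the cancer
probability ``p``. The counts are then weighted, ``[normal*(1-p),
benign*(1-p), insitu*p, invasive*p]``, an attention-like reweighting that
suppresses cross-superclass confusion, and stage two — softmax over the
weighted counts, dense(4, sigmoid), dense(4, softmax) — yields the final
four-class probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from histopatch import nn
from histopatch.io_dataset import CLASSES, CLASS_TO_INDEX, CANCEROUS
from histopatch.ensemble import PatchClassProbabilities
from histopatch.nn import TrainConfig


@dataclass
class FrequencyArray:
    """Per-image patch-class counts (4-class, 2-class, optionally weighted)."""

    image_ref: str
    counts4: np.ndarray  # [normal, benign, insitu, invasive]
    counts2: np.ndarray  # [cancerous, noncancerous]
    total: int
    weighted4: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts4 = np.asarray(self.counts4)
        self.counts2 = np.asarray(self.counts2)
        if self.counts4.sum() != self.total or self.counts2.sum() != self.total:
            raise ValueError(
                f"image {self.image_ref}: counts do not sum to total "
                f"({self.counts4.sum()}, {self.counts2.sum()} vs {self.total})"
            )


@dataclass
class ImagePrediction:
    image_ref: str
    cancer_probability: float
    class_probs: np.ndarray
    predicted_class: str
    predicted_cancerous: bool


def parent_of(patch_ref: str) -> str:
    """Parent image id from a ``{parent}_r{row}_c{col}`` patch id."""
    if "_r" not in patch_ref:
        raise ValueError(f"patch ref {patch_ref!r} does not encode a parent id")
    return patch_ref.rsplit("_r", 1)[0]


def group_by_parent(preds: list[PatchClassProbabilities]) -> dict[str, list[PatchClassProbabilities]]:
    groups: dict[str, list[PatchClassProbabilities]] = {}
    for p in preds:
        groups.setdefault(parent_of(p.patch_ref), []).append(p)
    return groups


def build_frequency_array(
    patch_preds: list[PatchClassProbabilities],
    expected_total: int | None = None,
    soft: bool = False,
) -> FrequencyArray:
    """Count patch argmax classes (hard counting; ``soft=True`` sums the
    probability vectors instead) for the patches of a single image."""
    if not patch_preds:
        raise ValueError("no patch predictions to aggregate")
    parents = {parent_of(p.patch_ref) for p in patch_preds}
    if len(parents) != 1:
        raise ValueError(f"patch predictions mix parent images: {sorted(parents)}")
    if expected_total is not None and len(patch_preds) != expected_total:
        raise ValueError(
            f"image {parents.copy().pop()}: expected {expected_total} patches, got {len(patch_preds)}"
        )
    if soft:
        counts4 = np.sum([p.probs for p in patch_preds], axis=0)
    else:
        counts4 = np.zeros(len(CLASSES), dtype=int)
        for p in patch_preds:
            counts4[p.predicted_index] += 1
    cancer_idx = [CLASS_TO_INDEX[c] for c in sorted(CANCEROUS, key=CLASS_TO_INDEX.get)]
    noncancer_idx = [i for i in range(len(CLASSES)) if i not in cancer_idx]
    counts2 = np.array([counts4[cancer_idx].sum(), counts4[noncancer_idx].sum()])
    return FrequencyArray(
        image_ref=parents.pop(),
        counts4=counts4,
        counts2=counts2,
        total=len(patch_preds),
    )


def weight_frequency(freq: FrequencyArray, p_cancer: float) -> FrequencyArray:
    """Weight counts4 by the cancer probability:
    ``[normal*(1-p), benign*(1-p), insitu*p, invasive*p]``.

    The weighted array is kept pre-softmax; the four-class network applies
    the softmax normalization as its input layer.
    """
    if not 0.0 <= p_cancer <= 1.0:
        raise ValueError(f"p_cancer must be in [0, 1], got {p_cancer}")
    w = np.array([1 - p_cancer, 1 - p_cancer, p_cancer, p_cancer])
    return replace(freq, weighted4=freq.counts4 * w)


# ---------------------------------------------------------------------------
# the two stage models


class TwoClassModel:
    """softmax(counts2) -> one L2-regularized affine unit -> sigmoid.

    Note a representational quirk inherited from the architecture: softmax
    over raw counts is scale-invariant only in differences, so all balanced
    arrays (k, k) map to the same input (0.5, 0.5) and receive identical
    probabilities.
    """

    def __init__(self, l2: float = 1e-3, seed: int = 0) -> None:
        rng = np.random.default_rng(seed)
        self.net = nn.Sequential(
            [nn.Softmax(), nn.Dense(2, 1, l2=l2, rng=rng)],
            loss="binary_crossentropy",
        )
        self.trained = False

    def fit(self, freqs: list[FrequencyArray], cancerous: list[bool], cfg: TrainConfig) -> pd.DataFrame:
        x = np.stack([f.counts2 for f in freqs]).astype(float)
        y = np.asarray(cancerous, dtype=float).reshape(-1, 1)
        history = self.net.fit(x, y, cfg)
        self.trained = True
        return history

    def predict_p(self, freq: FrequencyArray) -> float:
        return float(self.net.predict_proba(freq.counts2[None].astype(float))[0, 0])

    def predict_batch(self, freqs: list[FrequencyArray]) -> np.ndarray:
        x = np.stack([f.counts2 for f in freqs]).astype(float)
        return self.net.predict_proba(x)[:, 0]


class OracleTwoClassModel:
    """Ground-truth binary stage (p = 1 for truly cancerous images): the
    reference point for checking that four-class errors stay within a
    superclass when the binary stage is perfect."""

    def __init__(self, cancerous_by_image: dict[str, bool]) -> None:
        self._truth = cancerous_by_image
        self.trained = True

    def predict_p(self, freq: FrequencyArray) -> float:
        return 1.0 if self._truth[freq.image_ref] else 0.0


class FourClassModel:
    """softmax(weighted counts) -> dense(4, sigmoid) -> dense(4, softmax)."""

    def __init__(self, l2: float = 1e-4, seed: int = 0) -> None:
        rng = np.random.default_rng(seed)
        n = len(CLASSES)
        self.net = nn.Sequential(
            [
                nn.Softmax(),
                nn.Dense(n, n, activation="sigmoid", l2=l2, rng=rng),
                nn.Dense(n, n, rng=rng),
            ],
            loss="categorical_crossentropy",
        )
        self.trained = False

    def fit(self, weighted: list[FrequencyArray], labels: list[str], cfg: TrainConfig) -> pd.DataFrame:
        x = np.stack([f.weighted4 for f in weighted]).astype(float)
        y = np.zeros((len(labels), len(CLASSES)))
        y[np.arange(len(labels)), [CLASS_TO_INDEX[l] for l in labels]] = 1.0
        history = self.net.fit(x, y, cfg)
        self.trained = True
        return history

    def predict_probs(self, freq: FrequencyArray) -> np.ndarray:
        if freq.weighted4 is None:
            raise ValueError(f"image {freq.image_ref}: weighted counts not computed")
        return self.net.predict_proba(freq.weighted4[None].astype(float))[0]


def train_two_class(
    freqs: list[FrequencyArray], cancerous: list[bool], cfg: TrainConfig, l2: float = 1e-3
) -> tuple[TwoClassModel, pd.DataFrame]:
    """Fit the binary cancer stage by binary cross-entropy with Adam."""
    if len(set(map(bool, cancerous))) < 2:
        raise ValueError("two-class training needs both cancerous and non-cancerous images")
    model = TwoClassModel(l2=l2, seed=cfg.seed)
    history = model.fit(freqs, cancerous, cfg)
    return model, history


def train_four_class(
    weighted: list[FrequencyArray], labels: list[str], cfg: TrainConfig, l2: float = 1e-4
) -> tuple[FourClassModel, pd.DataFrame]:
    """Fit the final four-class stage by cross-entropy with Adam and the
    iterative lr-decay schedule."""
    if set(labels) != set(CLASSES):
        raise ValueError(f"four-class training needs all classes, got {sorted(set(labels))}")
    model = FourClassModel(l2=l2, seed=cfg.seed)
    history = model.fit(weighted, labels, cfg)
    return model, history


def predict_image(
    patch_preds: list[PatchClassProbabilities],
    two_class_model,
    four_class_model: FourClassModel,
    expected_total: int | None = None,
) -> ImagePrediction:
    """Full chain: counts -> cancer probability -> weighted counts -> class
    probabilities; binary call at p > 0.5, class call at argmax."""
    freq = build_frequency_array(patch_preds, expected_total=expected_total)
    p = float(two_class_model.predict_p(freq))
    weighted = weight_frequency(freq, p)
    class_probs = four_class_model.predict_probs(weighted)
    return ImagePrediction(
        image_ref=freq.image_ref,
        cancer_probability=p,
        class_probs=class_probs,
        predicted_class=CLASSES[int(class_probs.argmax())],
        predicted_cancerous=p > 0.5,
    )


def majority_vote_class(freq: FrequencyArray) -> str:
    """Baseline image prediction: the modal patch class (ties to the lowest
    class index)."""
    return CLASSES[int(np.asarray(freq.counts4).argmax())]


def image_predictions_table(preds: list[ImagePrediction]) -> pd.DataFrame:
    """``image_id,p_cancer,p_normal,...,pred4,pred2`` for persistence."""
    rows = [
        (
            p.image_ref,
            p.cancer_probability,
            *p.class_probs,
            p.predicted_class,
            "cancerous" if p.predicted_cancerous else "noncancerous",
        )
        for p in preds
    ]
    return pd.DataFrame(
        rows,
        columns=["image_id", "p_cancer"] + [f"p_{c}" for c in CLASSES] + ["pred4", "pred2"],
    )
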