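"""Per-patch feature extraction: pluggable backbone + trainable head.

A backbone maps a 512x512x3 patch to a spatial feature map; the fine-tuning
head (3x3 conv with 512 kernels -> 2x2 max pool -> global average pooling
-> batch norm -> dropout -> dense 64, sigmoid, He-uniform, L2 -> dense 4 ->
softmax) is trained on labelled patches with Adam, cross-entropy loss, the
iterative lr-decay schedule, and early stopping on validation accuracy.
After training, patch features are read at the GAP output — 512 dimensions
for the standard head — and concatenated across backbones.

Backbones are an interface, not a dependency: the bundled tiny CNN backbone
(fixed random filters over a block-averaged input) needs no pretrained
weights and carries the whole test path; adapters for ImageNet-pretrained
backbones activate only when a keras runtime is importable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from histopatch import nn
from histopatch.io_dataset import CLASSES, CLASS_TO_INDEX
from histopatch.nn import TrainConfig  # re-exported
from histopatch.patching import PatchRecord

__all__ = [
    "BackboneInterface",
    "TinyBackbone",
    "KerasBackbone",
    "FineTuneHead",
    "TrainConfig",
    "FeatureVector",
    "head_forward",
    "train_head",
    "extract_features",
    "concat_features",
    "cross_entropy",
    "categorical_accuracy",
    "one_hot",
]


@dataclass
class FeatureVector:
    patch_ref: str
    values: np.ndarray
    source: str


def one_hot(labels, n_classes: int = len(CLASSES)) -> np.ndarray:
    """Class names or integer indices -> one-hot rows."""
    idx = np.array([CLASS_TO_INDEX[l] if isinstance(l, str) else int(l) for l in labels])
    out = np.zeros((len(idx), n_classes))
    out[np.arange(len(idx)), idx] = 1.0
    return out


def cross_entropy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """``-sum(y_true * log(y_pred))`` with natural log and an eps guard."""
    y_pred = np.clip(np.asarray(y_pred, dtype=float), 1e-12, None)
    return float(-np.sum(np.asarray(y_true, dtype=float) * np.log(y_pred)))


def categorical_accuracy(y_true, y_pred: np.ndarray) -> float:
    """Fraction of samples whose argmax prediction matches the label.

    ``y_true`` may be class names, integer indices, or one-hot rows. Argmax
    ties break to the lowest class index.
    """
    y_pred = np.atleast_2d(np.asarray(y_pred, dtype=float))
    if len(y_pred) == 0:
        raise ValueError("categorical_accuracy of empty input")
    y_true = np.asarray(y_true)
    if y_true.ndim == 2:
        truth = y_true.argmax(axis=1)
    else:
        truth = np.array([CLASS_TO_INDEX[l] if isinstance(l, str) else int(l) for l in y_true])
    if len(truth) != len(y_pred):
        raise ValueError(f"length mismatch: {len(truth)} labels vs {len(y_pred)} predictions")
    return float(np.mean(y_pred.argmax(axis=1) == truth))


# ---------------------------------------------------------------------------
# backbones


class BackboneInterface:
    """A backbone exposes ``embed`` (patches -> NHWC feature maps), a channel
    count, a name, and the number of terminal layers left trainable."""

    name: str = "backbone"
    channels: int = 0
    trainable_depth: int = 0

    def embed(self, patches: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class TinyBackbone(BackboneInterface):
    """A ~7k-parameter fixed CNN: block-average the patch by ``downsample``,
    then two random He-initialized 3x3 conv + 2x2 pool blocks. Deterministic
    given ``seed``; never trained — the head on top is the trained part."""

    def __init__(self, seed: int = 0, downsample: int = 16, channels: tuple[int, int] = (16, 32)) -> None:
        rng = np.random.default_rng(seed)
        self.name = "tiny"
        self.downsample = downsample
        self.trainable_depth = 0
        self._conv1 = nn.Conv2D(3, channels[0], activation="relu", rng=rng)
        self._conv2 = nn.Conv2D(channels[0], channels[1], activation="relu", rng=rng)
        self._pool = nn.MaxPool2D()
        self.channels = channels[1]

    def embed(self, patches: np.ndarray) -> np.ndarray:
        x = np.asarray(patches, dtype=np.float64)
        single = x.ndim == 3
        if single:
            x = x[None]
        d = self.downsample
        n, h, w, c = x.shape
        hd, wd = h // d, w // d
        x = x[:, : hd * d, : wd * d, :].reshape(n, hd, d, wd, d, c).mean(axis=(2, 4))
        rng = np.random.default_rng(0)  # unused: no dropout in this stack
        maps = []
        for start in range(0, n, 64):  # bound peak memory
            z = x[start : start + 64]
            z = self._pool.forward(self._conv1.forward(z, False, rng), False, rng)
            z = self._pool.forward(self._conv2.forward(z, False, rng), False, rng)
            maps.append(z)
        out = np.concatenate(maps, axis=0)
        return out[0] if single else out


class KerasBackbone(BackboneInterface):
    """Adapter for ImageNet-pretrained backbones (VGG-16, VGG-19,
    Inception-ResNet v2). Requires a keras/tensorflow runtime with weights
    available; raises at construction otherwise. By default the last
    ``trainable_depth=4`` backbone layers are left unfrozen."""

    _FACTORIES = {
        "vgg16": ("keras.applications", "VGG16"),
        "vgg19": ("keras.applications", "VGG19"),
        "inception_resnet_v2": ("keras.applications", "InceptionResNetV2"),
    }

    def __init__(self, name: str, trainable_depth: int = 4) -> None:
        if name not in self._FACTORIES:
            raise ValueError(f"unknown pretrained backbone {name!r}; options: {sorted(self._FACTORIES)}")
        module_name, attr = self._FACTORIES[name]
        try:
            import importlib

            module = importlib.import_module(module_name)
        except ImportError as exc:
            raise RuntimeError(
                f"backbone {name!r} needs a keras runtime, which is not installed; "
                "use the 'tiny' backbone instead"
            ) from exc
        self._model = getattr(module, attr)(include_top=False, weights="imagenet")
        self.name = name
        self.trainable_depth = trainable_depth
        self.channels = int(self._model.output_shape[-1])
        for layer in self._model.layers[: len(self._model.layers) - trainable_depth]:
            layer.trainable = False

    def embed(self, patches: np.ndarray) -> np.ndarray:
        x = np.asarray(patches, dtype=np.float32)
        if x.ndim == 3:
            return np.asarray(self._model(x[None]))[0]
        return np.asarray(self._model.predict(x, verbose=0))


# ---------------------------------------------------------------------------
# fine-tuning head


class FineTuneHead:
    """The trainable head over a backbone feature map.

    Layer order: conv(512 kernels, 3x3, stride 1, ReLU) -> max pool (2x2,
    stride 2) -> GAP -> batch norm -> dropout(0.4) -> dense(64, sigmoid,
    He-uniform, L2) -> dense(4) -> softmax. Features are tapped at the GAP
    output, so their length equals the conv channel count (512 for the
    standard head).
    """

    GAP_INDEX = 2  # layer index whose output is the feature tap

    def __init__(
        self,
        in_channels: int,
        conv_channels: int = 512,
        dense_units: int = 64,
        n_classes: int = len(CLASSES),
        dropout: float = 0.4,
        l2: float = 1e-4,
        seed: int = 0,
    ) -> None:
        rng = np.random.default_rng(seed)
        self.feature_dim = conv_channels
        self.trained = False
        self.net = nn.Sequential(
            [
                nn.Conv2D(in_channels, conv_channels, activation="relu", l2=l2, rng=rng),
                nn.MaxPool2D(),
                nn.GlobalAveragePool(),
                nn.BatchNorm(conv_channels),
                nn.Dropout(dropout),
                nn.Dense(conv_channels, dense_units, activation="sigmoid", l2=l2, init="he_uniform", rng=rng),
                nn.Dense(dense_units, n_classes, rng=rng),
            ],
            loss="categorical_crossentropy",
        )

    def forward(self, feature_maps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(class probabilities, GAP features) for a batch of NHWC maps."""
        x = np.asarray(feature_maps, dtype=np.float64)
        single = x.ndim == 3
        if single:
            x = x[None]
        rng = np.random.default_rng(0)
        feats = None
        for i, layer in enumerate(self.net.layers):
            x = layer.forward(x, False, rng)
            if i == self.GAP_INDEX:
                feats = x.copy()
        probs = nn.softmax(x, axis=-1)
        if single:
            return probs[0], feats[0]
        return probs, feats


def head_forward(feature_map: np.ndarray, head: FineTuneHead) -> tuple[np.ndarray, np.ndarray]:
    """Probabilities (4-vector, sums to 1) and GAP features for one map."""
    return head.forward(feature_map)


def _labels_of(patches: list[PatchRecord]) -> list[str]:
    return [p.label for p in patches]


def _check_all_classes(labels: list[str]) -> None:
    missing = [c for c in CLASSES if c not in set(labels)]
    if missing:
        raise ValueError(f"training patches missing classes: {missing}")


def train_head(
    backbone: BackboneInterface,
    head: FineTuneHead,
    patches: list[PatchRecord],
    valid: list[PatchRecord] | None,
    cfg: TrainConfig,
    augment_fn=None,
) -> tuple[FineTuneHead, pd.DataFrame]:
    """Train the head on backbone feature maps of labelled patches.

    Backbone maps are computed once and cached; with ``augment_fn(patches,
    rng) -> patches`` given, fresh augmented maps are embedded every epoch
    instead (on-the-fly mode). Early stopping monitors validation
    categorical accuracy when a validation set is supplied.
    """
    _check_all_classes(_labels_of(patches))
    y = one_hot(_labels_of(patches))
    maps = backbone.embed(np.stack([p.pixels for p in patches]))
    validation = None
    if valid:
        validation = (
            backbone.embed(np.stack([p.pixels for p in valid])),
            one_hot(_labels_of(valid)),
        )
    epoch_data_fn = None
    if augment_fn is not None:

        def epoch_data_fn(epoch: int, rng: np.random.Generator):
            if epoch == 0:
                return maps, y
            fresh = augment_fn(patches, rng)
            return backbone.embed(np.stack([p.pixels for p in fresh])), one_hot(_labels_of(fresh))

    history = head.net.fit(maps, y, cfg, validation=validation, epoch_data_fn=epoch_data_fn)
    head.trained = True
    return head, history


def extract_features(
    backbone: BackboneInterface,
    head: FineTuneHead,
    patches: list[PatchRecord],
    allow_untrained: bool = False,
) -> list[FeatureVector]:
    """GAP features, one vector per patch, order-aligned with the input."""
    if not head.trained and not allow_untrained:
        raise ValueError("head is untrained; pass allow_untrained=True for smoke use")
    maps = backbone.embed(np.stack([p.pixels for p in patches]))
    _, feats = head.forward(maps)
    return [
        FeatureVector(patch_ref=p.patch_id, values=feats[i], source=backbone.name)
        for i, p in enumerate(patches)
    ]


def concat_features(per_backbone: list[list[FeatureVector]]) -> list[FeatureVector]:
    """Concatenate aligned per-backbone feature lists patchwise."""
    if not per_backbone:
        raise ValueError("no feature lists to concatenate")
    if len(per_backbone) == 1:
        return per_backbone[0]
    first = per_backbone[0]
    for other in per_backbone[1:]:
        if len(other) != len(first):
            raise ValueError("feature lists have different lengths")
        for a, b in zip(first, other):
            if a.patch_ref != b.patch_ref:
                raise ValueError(f"misaligned patch identities: {a.patch_ref!r} vs {b.patch_ref!r}")
    return [
        FeatureVector(
            patch_ref=first[i].patch_ref,
            values=np.concatenate([lst[i].values for lst in per_backbone]),
            source="concat",
        )
        for i in range(len(first))
    ]


def features_to_matrix(features: list[FeatureVector]) -> np.ndarray:
    return np.stack([f.values for f in features])
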