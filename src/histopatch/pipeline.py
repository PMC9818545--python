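"""End-to-end orchestration: split -> patch -> stain-normalize -> train patch
model -> extract features -> classifier bank -> fuse -> frequency arrays ->
two-class net -> weighted counts -> four-class net -> evaluate.

Every stage seed derives deterministically from the single global seed, and
all artifacts (splits, template stain model, training histories, prediction
tables, metric reports, the resolved config) are written under a run
directory, so two runs with the same config and seed produce identical
prediction CSVs.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from histopatch import aggregation, ensemble, features as feat, io_dataset, metrics, patching, stain, synthetic
from histopatch.augment import AugmentSpec, expand_training_patches
from histopatch.io_dataset import CLASSES, ImageRecord, SplitSpec, is_cancerous
from histopatch.nn import TrainConfig

log = logging.getLogger("histopatch")

STAGES = ("split", "patch", "stain", "patch_model", "features", "ensemble", "image_model", "evaluate")


def stage_seed(global_seed: int, stage_index: int) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return int(np.random.SeedSequence([global_seed & 0x7FFFFFFF, stage_index]).generate_state(1)[0] % (2**31))


@dataclass
class FixtureConfig:
    enabled: bool = True
    profile: str = "easy"  # "easy" or "default"
    n_per_class: int = 6
    height: int = 768
    width: int = 1280
    noise_sd: float = 0.0


@dataclass
class StainConfig:
    enabled: bool = True
    od_threshold: float = stain.OD_THRESHOLD
    angle_percentile: float = stain.ANGLE_PERCENTILE
    template: str | None = None  # path to a patch raster; default: first training patch
    method: str = "nnls"
    fallback_passthrough: bool = True


@dataclass
class AugmentConfig:
    enabled: bool = True
    n_copies: int = 1
    p_hflip: float = 0.5
    p_vflip: float = 0.5
    max_rotation_degrees: float = 15.0
    max_translation_fraction: float = 0.1
    fill_mode: str = "reflect"


@dataclass
class PipelineConfig:
    """The single configuration object driving :func:`run_pipeline`."""

    manifest: str | None = None
    out_dir: str = "runs/run0"
    seed: int = 0
    fixtures: FixtureConfig = field(default_factory=FixtureConfig)
    split: dict = field(default_factory=lambda: {"train_fraction": 0.65, "validation_fraction": 0.15, "test_fraction": 0.20, "stratified": True})
    patch_size: int = patching.PATCH_SIZE
    patch_stride: int = patching.PATCH_STRIDE
    stain: StainConfig = field(default_factory=StainConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    backbones: list[str] = field(default_factory=lambda: ["tiny"])
    patch_train: dict = field(default_factory=lambda: {"lr0": 0.008, "max_epochs": 60, "early_stop_patience": 5, "dropout": 0.4, "adam_beta1": 0.8, "adam_beta2": 0.99})
    image_train: dict = field(default_factory=lambda: {"lr0": 0.008, "max_epochs": 400, "batch_size": 16, "adam_beta1": 0.8, "adam_beta2": 0.99})
    ensemble_rule: str = "average"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        for name, sub in (("fixtures", FixtureConfig), ("stain", StainConfig), ("augment", AugmentConfig)):
            if name in kwargs and isinstance(kwargs[name], dict):
                kwargs[name] = sub(**kwargs[name])
        return cls(**kwargs)


@dataclass
class PipelineResult:
    records: list[ImageRecord]
    template: stain.StainModel | None
    patch_history: pd.DataFrame | None
    member_accuracies: dict[str, float]
    fused_patch_accuracy: float | None
    patch_report: metrics.MetricsReport | None
    image_predictions: list[aggregation.ImagePrediction]
    image_report4: metrics.MetricsReport | None
    image_report2: metrics.MetricsReport | None
    majority_baseline_accuracy: float | None
    out_dir: Path
    two_class_model: aggregation.TwoClassModel | None = None
    four_class_model: aggregation.FourClassModel | None = None
    test_patch_predictions: list = field(default_factory=list)


def _load_records(config: PipelineConfig) -> list[ImageRecord]:
    if config.manifest:
        return io_dataset.load_manifest(config.manifest)
    fx = config.fixtures
    if not fx.enabled:
        raise ValueError("no manifest given and fixtures disabled: nothing to run on")
    fseed = stage_seed(config.seed, 100)
    if fx.profile == "easy":
        spec = synthetic.FixtureSpec.easy(
            n_per_class=fx.n_per_class, height=fx.height, width=fx.width, seed=fseed, noise_sd=fx.noise_sd
        )
    else:
        spec = synthetic.FixtureSpec(
            n_per_class=fx.n_per_class, height=fx.height, width=fx.width, seed=fseed, noise_sd=fx.noise_sd
        )
    return synthetic.make_dataset(spec)


def _make_backbone(name: str, seed: int) -> feat.BackboneInterface:
    if name == "tiny":
        return feat.TinyBackbone(seed=seed)
    return feat.KerasBackbone(name)


def run_pipeline(config: PipelineConfig, stop_after: str | None = None) -> PipelineResult:
    """Execute the pipeline; see the module docstring for the stage chain.

    ``stop_after`` halts early after the named stage (one of ``STAGES``),
    still writing that stage's artifacts.
    """
    if stop_after is not None and stop_after not in STAGES:
        raise ValueError(f"unknown stage {stop_after!r}; options: {STAGES}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    t0 = time.time()

    def done(stage: str, **info) -> bool:
        log.info("stage=%s elapsed=%.1fs %s", stage, time.time() - t0, " ".join(f"{k}={v}" for k, v in info.items()))
        return stop_after == stage

    result = PipelineResult(
        records=[], template=None, patch_history=None, member_accuracies={},
        fused_patch_accuracy=None, patch_report=None, image_predictions=[],
        image_report4=None, image_report2=None, majority_baseline_accuracy=None, out_dir=out,
    )

    # ---- split -------------------------------------------------------
    records = _load_records(config)
    spec = SplitSpec(seed=stage_seed(config.seed, 0), **config.split)
    records = io_dataset.make_splits(records, spec)
    io_dataset.save_splits(records, out / "splits.csv")
    result.records = records
    if done("split", images=len(records)):
        return result

    # ---- patch -------------------------------------------------------
    patches: dict[str, list[patching.PatchRecord]] = {"train": [], "validation": [], "test": []}
    for rec in records:
        patches[rec.split].extend(patching.extract_patches(rec, config.patch_size, config.patch_stride))
    if done("patch", **{k: len(v) for k, v in patches.items()}):
        return result

    # ---- stain normalization ----------------------------------------
    template = None
    if config.stain.enabled:
        if config.stain.template:
            template_pixels = io_dataset.load_image(config.stain.template, "normal").pixels
        else:
            # first patch (row 0, col 0) of the first training image in manifest order
            first_train = next(r for r in records if r.split == "train")
            template_pixels = next(
                p for p in patches["train"] if p.parent_id == first_train.image_id and p.row == 0 and p.col == 0
            ).pixels
        template = stain.estimate_stains(
            template_pixels, config.stain.od_threshold, config.stain.angle_percentile
        )
        template.to_json(out / "template_stain_model.json")
        for split_name, plist in patches.items():
            patches[split_name] = [
                stain.normalize_to_template(
                    p,
                    template,
                    config.stain.od_threshold,
                    config.stain.angle_percentile,
                    method=config.stain.method,
                    fallback_passthrough=config.stain.fallback_passthrough,
                )
                for p in plist
            ]
        result.template = template
    if done("stain"):
        return result

    # ---- augmentation (training stream only) ------------------------
    train_patches = patches["train"]
    if config.augment.enabled and config.augment.n_copies > 0:
        aug_spec = AugmentSpec(
            p_hflip=config.augment.p_hflip,
            p_vflip=config.augment.p_vflip,
            max_rotation_degrees=config.augment.max_rotation_degrees,
            max_translation_fraction=config.augment.max_translation_fraction,
            fill_mode=config.augment.fill_mode,
            seed=stage_seed(config.seed, 1),
        )
        train_patches = expand_training_patches(train_patches, aug_spec, config.augment.n_copies)

    # ---- patch model(s): train head, extract + concatenate features -
    per_backbone_train, per_backbone_val, per_backbone_test = [], [], []
    patch_history = None
    for bi, backbone_name in enumerate(config.backbones):
        bseed = stage_seed(config.seed, 10 + bi)
        backbone = _make_backbone(backbone_name, bseed)
        head = feat.FineTuneHead(backbone.channels, seed=bseed)
        cfg = TrainConfig(seed=bseed, **config.patch_train)
        head, history = feat.train_head(backbone, head, train_patches, patches["validation"] or None, cfg)
        history.to_csv(out / f"patch_model_history_{backbone_name}.csv", index=False)
        patch_history = history
        per_backbone_train.append(feat.extract_features(backbone, head, train_patches))
        if patches["validation"]:
            per_backbone_val.append(feat.extract_features(backbone, head, patches["validation"]))
        if patches["test"]:
            per_backbone_test.append(feat.extract_features(backbone, head, patches["test"]))
    result.patch_history = patch_history
    if done("patch_model", epochs=0 if patch_history is None else len(patch_history)):
        return result

    train_features = feat.concat_features(per_backbone_train)
    val_features = feat.concat_features(per_backbone_val) if per_backbone_val else []
    test_features = feat.concat_features(per_backbone_test) if per_backbone_test else []
    np.savez(
        out / "train_features.npz",
        features=feat.features_to_matrix(train_features),
        patch_ids=np.array([f.patch_ref for f in train_features]),
        labels=np.array([p.label for p in train_patches]),
    )
    if done("features", dim=len(train_features[0].values)):
        return result

    # ---- classifier bank + fusion -----------------------------------
    bank = ensemble.fit_bank(train_features, [p.label for p in train_patches], seed=stage_seed(config.seed, 2))

    def fuse_features(features_list):
        per_member = ensemble.predict_bank(bank, features_list)
        return per_member, ensemble.fuse(
            [per_member[n] for n in ensemble.CLASSIFIER_NAMES], config.ensemble_rule
        )

    fused_test = []
    if patches["test"]:
        test_labels = [p.label for p in patches["test"]]
        per_member, fused_test = fuse_features(test_features)
        result.member_accuracies = {
            name: feat.categorical_accuracy(test_labels, np.stack([p.probs for p in preds]))
            for name, preds in per_member.items()
        }
        result.fused_patch_accuracy = feat.categorical_accuracy(
            test_labels, np.stack([p.probs for p in fused_test])
        )
        result.patch_report = metrics.evaluate(
            [io_dataset.CLASS_TO_INDEX[l] for l in test_labels],
            [p.predicted_index for p in fused_test],
        )
        result.patch_report.to_json(out / "patch_report.json")
        meta = {p.patch_id: (p.parent_id, p.row, p.col) for p in patches["test"]}
        ensemble.predictions_table(fused_test, meta).to_csv(out / "patch_predictions.csv", index=False)
    if done("ensemble", fused_acc=result.fused_patch_accuracy):
        return result

    # ---- image stage: frequency arrays + two-stage network ----------
    # validation images merge into training for the image-level models
    merged = io_dataset.merge_validation_into_train(records)
    image_train_patches = patches["train"] + patches["validation"]
    image_train_features = train_features[: len(patches["train"])] + val_features
    fused_by_parent = aggregation.group_by_parent(fuse_features(image_train_features)[1])
    train_images = [r for r in merged if r.split == "train"]
    freqs = [aggregation.build_frequency_array(fused_by_parent[r.image_id]) for r in train_images]
    binary = [is_cancerous(r.label) for r in train_images]
    img_cfg = TrainConfig(seed=stage_seed(config.seed, 3), **config.image_train)
    two_model, hist2 = aggregation.train_two_class(freqs, binary, img_cfg)
    hist2.to_csv(out / "two_class_history.csv", index=False)
    weighted = [aggregation.weight_frequency(f, p) for f, p in zip(freqs, two_model.predict_batch(freqs))]
    four_cfg = TrainConfig(seed=stage_seed(config.seed, 4), **config.image_train)
    four_model, hist4 = aggregation.train_four_class(weighted, [r.label for r in train_images], four_cfg)
    hist4.to_csv(out / "four_class_history.csv", index=False)
    result.two_class_model = two_model
    result.four_class_model = four_model
    result.test_patch_predictions = fused_test
    if done("image_model"):
        return result

    # ---- evaluate on the test images --------------------------------
    test_images = [r for r in records if r.split == "test"]
    if not test_images:
        raise ValueError("evaluation stage: no test images (test_fraction is 0?)")
    fused_test_by_parent = aggregation.group_by_parent(fused_test)
    preds, majority_hits = [], 0
    for rec in test_images:
        patch_preds = fused_test_by_parent[rec.image_id]
        preds.append(aggregation.predict_image(patch_preds, two_model, four_model))
        freq = aggregation.build_frequency_array(patch_preds)
        majority_hits += aggregation.majority_vote_class(freq) == rec.label
    aggregation.image_predictions_table(preds).to_csv(out / "image_predictions.csv", index=False)
    truth4 = [io_dataset.CLASS_TO_INDEX[r.label] for r in test_images]
    result.image_predictions = preds
    result.image_report4 = metrics.evaluate(truth4, [io_dataset.CLASS_TO_INDEX[p.predicted_class] for p in preds])
    result.image_report4.to_json(out / "image_report_4class.json")
    result.image_report2 = metrics.evaluate(
        [int(is_cancerous(r.label)) for r in test_images],
        [int(p.predicted_cancerous) for p in preds],
        class_names=("noncancerous", "cancerous"),
    )
    result.image_report2.to_json(out / "image_report_2class.json")
    result.majority_baseline_accuracy = majority_hits / len(test_images)
    log.info(
        "majority-vote baseline %.3f vs two-stage %.3f",
        result.majority_baseline_accuracy,
        result.image_report4.overall_accuracy,
    )
    done("evaluate", acc4=result.image_report4.overall_accuracy, acc2=result.image_report2.overall_accuracy)
    return result
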