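"""Labelled image collections, pixel scaling, and train/validation/test splits.

Images carry one of four tissue labels — normal, benign, in situ carcinoma,
invasive carcinoma — and 8-bit pixels are scaled to [0, 1] on load. The
default partition is 65/15/20 train/validation/test, stratified by class;
for the image-level stage the validation images are merged back into
training.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import imageio.v3 as iio
import tifffile

#: Canonical class order. Superclasses: non-cancerous = {normal, benign},
#: cancerous = {insitu, invasive}.
CLASSES: tuple[str, ...] = ("normal", "benign", "insitu", "invasive")

CLASS_TO_INDEX = {c: i for i, c in enumerate(CLASSES)}

#: Classes whose images count as cancerous at the binary stage.
CANCEROUS = frozenset({"insitu", "invasive"})

_LABEL_ALIASES = {
    "normal": "normal",
    "benign": "benign",
    "insitu": "insitu",
    "in situ": "insitu",
    "in_situ": "insitu",
    "invasive": "invasive",
}


def canonical_label(label: str) -> str:
    """Map a label spelling (e.g. ``"in situ"``) to its canonical form."""
    key = label.strip().lower()
    if key not in _LABEL_ALIASES:
        raise ValueError(f"unknown class label {label!r}; expected one of {CLASSES}")
    return _LABEL_ALIASES[key]


def is_cancerous(label: str) -> bool:
    return canonical_label(label) in CANCEROUS


@dataclass
class ImageRecord:
    """One labelled histology image with pixels scaled to [0, 1]."""

    image_id: str
    pixels: np.ndarray  # H x W x 3 float32 in [0, 1]
    label: str
    split: str = "unassigned"

    def __post_init__(self) -> None:
        self.label = canonical_label(self.label)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"image {self.image_id!r}: expected HxWx3 pixels, got shape {self.pixels.shape}"
            )

    @property
    def label_index(self) -> int:
        return CLASS_TO_INDEX[self.label]


@dataclass(frozen=True)
class SplitSpec:
    """Fractions and seed for the train/validation/test partition."""

    train_fraction: float = 0.65
    validation_fraction: float = 0.15
    test_fraction: float = 0.20
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        fracs = (self.train_fraction, self.validation_fraction, self.test_fraction)
        if any(f < 0 for f in fracs):
            raise ValueError(f"split fractions must be nonnegative, got {fracs}")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {fracs} (sum {sum(fracs)})")


def load_image(path: str | Path, label: str, image_id: str | None = None) -> ImageRecord:
    """Read an 8-bit RGB raster (TIFF or PNG) and scale pixels to [0, 1]."""
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            raw = tifffile.imread(path)
        else:
            raw = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    raw = np.asarray(raw)
    if raw.ndim == 3 and raw.shape[2] == 4:  # drop alpha
        raw = raw[:, :, :3]
    if raw.ndim != 3 or raw.shape[2] != 3:
        raise ValueError(f"{path}: expected a 3-channel RGB raster, got shape {raw.shape}")
    if raw.dtype == np.uint8:
        pixels = raw.astype(np.float32) / 255.0
    elif raw.dtype == np.uint16:
        pixels = raw.astype(np.float32) / 65535.0
    else:  # already float: trust but clip
        pixels = np.clip(raw.astype(np.float32), 0.0, 1.0)
    return ImageRecord(image_id=image_id or path.stem, pixels=pixels, label=label)


def load_manifest(manifest_csv: str | Path, root: str | Path | None = None) -> list[ImageRecord]:
    """Load every image listed in a ``path,label`` manifest CSV."""
    manifest_csv = Path(manifest_csv)
    table = pd.read_csv(manifest_csv)
    if not {"path", "label"} <= set(table.columns):
        raise ValueError(f"{manifest_csv}: manifest needs columns 'path' and 'label'")
    base = Path(root) if root is not None else manifest_csv.parent
    records = []
    for row in table.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        records.append(load_image(p, row.label))
    return records


def _largest_remainder_counts(n: int, fractions: Sequence[float]) -> list[int]:
    """Integer split sizes summing to n, by the largest-remainder rule."""
    exact = [n * f for f in fractions]
    counts = [int(np.floor(e)) for e in exact]
    remainders = [e - c for e, c in zip(exact, counts)]
    # hand leftover seats to the largest remainders; ties go to earlier splits
    for i in sorted(range(len(fractions)), key=lambda i: (-remainders[i], i))[: n - sum(counts)]:
        counts[i] += 1
    return counts


def make_splits(records: Sequence[ImageRecord], spec: SplitSpec) -> list[ImageRecord]:
    """Assign each record to train/validation/test.

    Stratified by class when ``spec.stratified``; sizes follow the fractions
    with largest-remainder rounding per class; deterministic given
    ``spec.seed``. Returns new records (input untouched).
    """
    fractions = (spec.train_fraction, spec.validation_fraction, spec.test_fraction)
    names = ("train", "validation", "test")
    rng = np.random.default_rng(spec.seed)
    out: dict[int, str] = {}
    if spec.stratified:
        groups: dict[str, list[int]] = {}
        for i, rec in enumerate(records):
            groups.setdefault(rec.label, []).append(i)
        group_items = sorted(groups.items())
    else:
        group_items = [("all", list(range(len(records))))]
    for _, idxs in group_items:
        idxs = np.array(idxs)
        rng.shuffle(idxs)
        counts = _largest_remainder_counts(len(idxs), fractions)
        start = 0
        for name, cnt in zip(names, counts):
            for i in idxs[start : start + cnt]:
                out[int(i)] = name
            start += cnt
    return [replace(rec, split=out[i]) for i, rec in enumerate(records)]


def merge_validation_into_train(records: Iterable[ImageRecord]) -> list[ImageRecord]:
    """Re-label every validation record as train (image-stage training set)."""
    return [
        replace(rec, split="train") if rec.split == "validation" else replace(rec)
        for rec in records
    ]


def split_table(records: Iterable[ImageRecord]) -> pd.DataFrame:
    """Tabulate ``image_id,label,split`` for persistence."""
    return pd.DataFrame(
        [(r.image_id, r.label, r.split) for r in records],
        columns=["image_id", "label", "split"],
    )


def save_splits(records: Iterable[ImageRecord], path: str | Path) -> None:
    split_table(records).to_csv(path, index=False)
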