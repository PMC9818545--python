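"""Overlapping fixed-size patch extraction with image-label propagation.

Each image is tiled with patch windows of ``patch`` pixels at a fixed
stride (default 512 at stride 256, i.e. 50% overlap); a 1536x2048 image
yields a 5x7 grid of 35 patches. Every patch inherits the label of its
parent image — label propagation accepts some noise for heterogeneous
tissue, since a cancerous image may contain predominantly healthy patches.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from histopatch.io_dataset import ImageRecord, canonical_label

PATCH_SIZE = 512
PATCH_STRIDE = 256


@dataclass
class PatchRecord:
    """One patch window: grid position, pixel offsets, pixels, inherited label."""

    parent_id: str
    row: int
    col: int
    y: int
    x: int
    pixels: np.ndarray
    label: str

    def __post_init__(self) -> None:
        self.label = canonical_label(self.label)

    @property
    def patch_id(self) -> str:
        return f"{self.parent_id}_r{self.row}_c{self.col}"


def patch_grid(height: int, width: int, patch: int = PATCH_SIZE, stride: int = PATCH_STRIDE) -> list[tuple[int, int]]:
    """Top-left (y, x) offsets of every full patch window, row-major.

    Offsets run over ``{0, stride, 2*stride, ...}`` in each axis subject to
    the window fitting entirely inside the image; any remainder margin is
    dropped (no padding — padding would fabricate tissue).
    """
    if patch > height or patch > width:
        raise ValueError(f"patch size {patch} exceeds image dimensions {height}x{width}")
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    ys = range(0, height - patch + 1, stride)
    xs = range(0, width - patch + 1, stride)
    return [(y, x) for y in ys for x in xs]


def grid_shape(height: int, width: int, patch: int = PATCH_SIZE, stride: int = PATCH_STRIDE) -> tuple[int, int]:
    """(rows, cols) of the patch grid: ``floor((dim - patch)/stride) + 1``."""
    if patch > height or patch > width:
        raise ValueError(f"patch size {patch} exceeds image dimensions {height}x{width}")
    return (height - patch) // stride + 1, (width - patch) // stride + 1


def extract_patches(image: ImageRecord, patch: int = PATCH_SIZE, stride: int = PATCH_STRIDE) -> list[PatchRecord]:
    """Cut an image into overlapping patches, each inheriting the image label."""
    height, width = image.pixels.shape[:2]
    _, n_cols = grid_shape(height, width, patch, stride)
    records = []
    for i, (y, x) in enumerate(patch_grid(height, width, patch, stride)):
        records.append(
            PatchRecord(
                parent_id=image.image_id,
                row=i // n_cols,
                col=i % n_cols,
                y=y,
                x=x,
                pixels=image.pixels[y : y + patch, x : x + patch].copy(),
                label=image.label,
            )
        )
    return records


def save_patches(patches: list[PatchRecord], out_dir: str | Path) -> Path:
    """Persist patches as TIFFs named ``{parent_id}_r{row}_c{col}.tiff`` plus
    a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in patches:
        fname = f"{p.patch_id}.tiff"
        tifffile.imwrite(out_dir / fname, (np.clip(p.pixels, 0, 1) * 255).round().astype(np.uint8))
        rows.append((fname, p.parent_id, p.row, p.col, p.y, p.x, p.label))
    manifest = out_dir / "patches.csv"
    pd.DataFrame(
        rows, columns=["path", "parent_id", "row", "col", "y", "x", "label"]
    ).to_csv(manifest, index=False)
    return manifest
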